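"""Post-detection testing of individual QTL-trait associations (idv).

Once a locus is claimed as a QTL, each of its k0 nontrivial effects is
tested given the other nontrivial effects (the trivial set is held at
zero), against the asymptotic chi-squared reference with one degree of
freedom at the Bonferroni-adjusted level alpha / k0.  Trivial effects are
excluded from testing and reported non-significant by construction, so the
two-step procedures (MBP+idv, All+idv, Seq+idv, BICdelta+idv) cannot claim
associations anywhere the detector claimed no QTL.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import core
from .detect import DetectionResult
from .io import DataError, GenotypeMatrix, PhenotypeMatrix


@dataclasses.dataclass(frozen=True)
class AssociationResult:
    """Locus x trait association tests for the claimed loci."""

    frame: pd.DataFrame  # columns: marker, trait, chi2, df, cutoff, significant, k0, trivial

    @property
    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["significant"]]


def idv_cutoff(alpha: float, k0: int, df: int = 1) -> float:
    """Bonferroni chi-squared cutoff chi2_df(1 - alpha / k0)."""
    if k0 < 1:
        raise DataError("k0 must be positive (nothing to test otherwise)")
    return float(sps.chi2.ppf(1.0 - alpha / k0, df))


def idv_test(geno_col: np.ndarray, Y: PhenotypeMatrix, trivial_set: Sequence[int],
             alpha: float, marker: str = "locus") -> AssociationResult:
    """Test each nontrivial effect at one claimed locus.

    For trait k outside the trivial set, the statistic compares the model
    with effects on all nontrivial traits against the same model with
    effect k constrained to zero; the cutoff is chi2_1(1 - alpha / k0)
    with k0 the number of nontrivial effects.
    """
    Ym = Y.values
    p = Ym.shape[1]
    trivial = sorted(set(int(t) for t in trivial_set))
    active = np.array([k for k in range(p) if k not in trivial], dtype=int)
    k0 = active.size
    if k0 == 0:
        raise DataError("empty nontrivial set: nothing to test")
    x = np.asarray(geno_col, dtype=float).ravel()
    ws = core.workspace_for_loci(Ym, x[:, None])
    t_active = ws.active_set_stat(active)[0]
    cutoff = idv_cutoff(alpha, k0)
    rows = []
    for k in range(p):
        if k in trivial:
            rows.append((marker, Y.trait_names[k], np.nan, 1, cutoff, False, k0, True))
            continue
        reduced = active[active != k]
        t_red = 0.0 if reduced.size == 0 else ws.active_set_stat(reduced)[0]
        chi2 = max(float(t_active - t_red), 0.0)
        rows.append((marker, Y.trait_names[k], chi2, 1, cutoff, chi2 > cutoff, k0, False))
    frame = pd.DataFrame(rows, columns=["marker", "trait", "chi2", "df", "cutoff",
                                        "significant", "k0", "trivial"])
    return AssociationResult(frame)


def two_step(detection: DetectionResult, geno: GenotypeMatrix,
             Y: PhenotypeMatrix, alpha: float) -> AssociationResult:
    """Apply idv at every locus the detector claimed.

    The trivial set at each claimed locus consists of the traits the
    detector eliminated (empty for All); unclaimed loci contribute no
    rows, so the familywise QTL error rate of the detector bounds the
    association claims.
    """
    p = Y.n_traits
    frames = []
    for l, claimed in enumerate(detection.claimed):
        if not claimed:
            continue
        kept = set(detection.trait_sets[l])
        trivial = [k for k in range(p) if k not in kept]
        col = geno.values[:, l]
        res = idv_test(col, Y, trivial, alpha, marker=detection.marker_id[l])
        frames.append(res.frame)
    if frames:
        frame = pd.concat(frames, ignore_index=True)
    else:
        frame = pd.DataFrame(columns=["marker", "trait", "chi2", "df", "cutoff",
                                      "significant", "k0", "trivial"])
    return AssociationResult(frame)


def association_matrix(assoc: AssociationResult, marker_id: Sequence[str],
                       trait_names: Sequence[str]) -> np.ndarray:
    """Boolean L x p matrix of significant associations."""
    out = np.zeros((len(marker_id), len(trait_names)), dtype=bool)
    midx = {m: i for i, m in enumerate(marker_id)}
    tidx = {t: j for j, t in enumerate(trait_names)}
    for _, row in assoc.significant.iterrows():
        out[midx[row["marker"]], tidx[row["trait"]]] = True
    return out
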