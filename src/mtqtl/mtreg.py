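"""Likelihood-ratio tests and genome scans for the multiple-trait QTL model.

The joint test of a putative QTL compares multivariate-normal regressions
with and without genotype effects on a chosen trait subset; statistics are
T = N * ln(det(Sigma0_hat) / det(Sigma1_hat)) with maximum-likelihood
(divide-by-N) covariance estimates, i.e. exactly -2 times the log-likelihood
difference of the nested fits.  Backward elimination orders the p effect
parameters at each locus by dropping, at every step, the effect whose
removal costs the joint statistic least, yielding the nested "best k
effects" statistics T_l1 <= ... <= T_lp used throughout the package.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import core
from .io import DataError, GenotypeMatrix, PhenotypeMatrix, validate_alignment


class SingularModelError(DataError):
    """Residual covariance cannot be estimated (singular design or traits)."""


def _check_inputs(geno_col: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(geno_col, dtype=float).ravel()
    Ym = Y.values if isinstance(Y, PhenotypeMatrix) else np.asarray(Y, dtype=float)
    if x.size != Ym.shape[0]:
        raise DataError("genotype column and phenotype rows differ in length")
    n, p = Ym.shape
    if n <= p + 2:
        raise SingularModelError(f"N={n} too small for p={p} traits")
    S = core.trait_cross_product(Ym)
    if not np.isfinite(core.batched_logdet(S[None])[0]):
        raise SingularModelError("singular trait cross-product (duplicated traits?)")
    return x, Ym


def _workspace(x: np.ndarray, Ym: np.ndarray) -> core.LocusWorkspace:
    if np.ptp(x) == 0:
        warnings.warn("monomorphic locus: statistic set to 0", stacklevel=3)
    return core.workspace_for_loci(Ym, x[:, None])


def lrt_joint(geno_col: np.ndarray, Y: PhenotypeMatrix | np.ndarray,
              active_set: Iterable[int] | None = None) -> float:
    """Joint LRT for genotype effects on the traits in `active_set`.

    `active_set` holds 0-based trait indices; None tests all traits.
    The statistic is asymptotically chi-squared with |active_set| degrees
    of freedom under the no-QTL null.
    """
    x, Ym = _check_inputs(geno_col, Y)
    p = Ym.shape[1]
    active = np.arange(p) if active_set is None else np.unique(np.asarray(list(active_set), dtype=int))
    if active.size < 1:
        raise DataError("active_set must contain at least one trait")
    if active.min() < 0 or active.max() >= p:
        raise DataError("active_set indices out of range")
    ws = _workspace(x, Ym)
    return float(ws.active_set_stat(active)[0])


def backward_eliminate(geno_col: np.ndarray, Y: PhenotypeMatrix | np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Best-k statistics and removal order at one locus.

    Returns (best_k_stats, elimination_order): best_k_stats[k-1] is the
    joint LRT of the k effects surviving after p-k removals; the order
    lists removed trait indices, first removal first.
    """
    x, Ym = _check_inputs(geno_col, Y)
    ws = _workspace(x, Ym)
    best, order = ws.backward_eliminate()
    return best[0], order[0]


@dataclasses.dataclass(frozen=True)
class ScanStatistics:
    """Genome-scan output: L x p best-k statistics and elimination orders."""

    stats: np.ndarray              # (L, p), nested nondecreasing per row
    elimination_order: np.ndarray  # (L, p) ints, first removed first
    marker_id: tuple[str, ...]

    def __post_init__(self):
        if np.any(self.stats < 0):
            raise DataError("scan statistics must be non-negative")
        if np.any(np.diff(self.stats, axis=1) < -1e-9):
            raise DataError("best-k statistics must be nondecreasing in k")

    @property
    def n_loci(self) -> int:
        return self.stats.shape[0]

    @property
    def n_traits(self) -> int:
        return self.stats.shape[1]

    @property
    def full_model_stat(self) -> np.ndarray:
        """T_lp, the all-effects statistic per locus."""
        return self.stats[:, -1]

    def best_k_sets(self, k0: np.ndarray) -> list[tuple[int, ...]]:
        """Surviving (nontrivial) trait sets for per-locus effect counts k0."""
        p = self.n_traits
        out = []
        for l, k in enumerate(np.asarray(k0, dtype=int)):
            out.append(tuple(sorted(self.elimination_order[l, p - k:])))
        return out

    def to_frame(self) -> pd.DataFrame:
        p = self.n_traits
        df = pd.DataFrame(self.stats, index=list(self.marker_id),
                          columns=[f"T{k}" for k in range(1, p + 1)])
        df["elimination_order"] = [
            " ".join(str(t) for t in row) for row in self.elimination_order]
        df.index.name = "marker"
        return df


def scan_genome(geno: GenotypeMatrix, Y: PhenotypeMatrix) -> ScanStatistics:
    """Backward elimination at every mapped locus."""
    Ym = Y.values
    if geno.n_individuals != Ym.shape[0]:
        raise DataError("genotype and phenotype rows differ")
    ws = core.workspace_for_loci(Ym, geno.values)
    best, order = ws.backward_eliminate()
    return ScanStatistics(best, order, tuple(geno.marker_id))


@dataclasses.dataclass(frozen=True)
class EffectTestStatistics:
    """Per-effect statistics: given-all-others (indiv) and alone (single)."""

    indiv: np.ndarray   # (L, p)
    single: np.ndarray  # (L, p)
    marker_id: tuple[str, ...]

    def __post_init__(self):
        if np.any(self.indiv < 0) or np.any(self.single < 0):
            raise DataError("effect statistics must be non-negative")


def effect_tests(geno: GenotypeMatrix, Y: PhenotypeMatrix) -> EffectTestStatistics:
    """Individual-effect and single-effect LRTs at every locus.

    indiv[l, k] tests effect k with all other effects retained (the joint
    full-model statistic minus the statistic without effect k); single[l, k]
    tests effect k with every other effect excluded.
    """
    ws = core.workspace_for_loci(Y.values, geno.values)
    return EffectTestStatistics(ws.individual_stats(), ws.single_effect_stats(),
                                tuple(geno.marker_id))


def lrt_given_trivial(geno_col: np.ndarray, Y: PhenotypeMatrix | np.ndarray,
                      k: int, trivial_set: Sequence[int]) -> float:
    """LRT for effect k with the trivial-set effects held at zero.

    Compares the model with effects on all traits outside `trivial_set`
    against the same model with effect k additionally constrained to zero
    (one degree of freedom).
    """
    trivial = set(int(t) for t in trivial_set)
    if k in trivial:
        raise DataError("tested trait must not be in the trivial set")
    x, Ym = _check_inputs(geno_col, Y)
    p = Ym.shape[1]
    active = np.array(sorted(set(range(p)) - trivial), dtype=int)
    ws = _workspace(x, Ym)
    t_with = ws.active_set_stat(active)[0]
    reduced = active[active != k]
    t_without = 0.0 if reduced.size == 0 else ws.active_set_stat(reduced)[0]
    return float(max(t_with - t_without, 0.0))
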