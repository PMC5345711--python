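"""QTL detection procedures: All, MBP, Indv, Seq and BIC_delta.

All five decide, per scanning locus, whether the locus is a QTL at a
genome-wide significance level, and report which trait effects were kept
nontrivial:

* All        — joint test of all p effects against lambda_p(alpha).
* MBP        — maximum bootstrap power: case-resample the individuals,
  compute the best-k statistics in each bootstrap sample, select the
  effect count k0 maximizing the bootstrap exceedance frequency f_k, and
  claim the locus when the original best-k0 statistic exceeds
  lambda_k0(alpha).
* Indv       — claim when any individual-effect statistic exceeds
  tau(alpha); the exceeding traits are the claimed associations.
* Seq        — sequential elimination with selection-bias-aware per-step
  thresholds.
* BIC_delta  — backward elimination with a fixed permutation-derived
  penalty; the locus is claimed when at least one effect is retained.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

from . import core
from .io import DataError, GenotypeMatrix, PhenotypeMatrix
from .mtreg import EffectTestStatistics, ScanStatistics, scan_genome
from .thresholds import ThresholdSet

logger = logging.getLogger("mtqtl")


@dataclasses.dataclass(frozen=True)
class BootstrapFrequency:
    """Bootstrap exceedance proportions f_k and selected counts k0 per locus."""

    fk: np.ndarray   # (L, p) in [0, 1]
    k0: np.ndarray   # (L,) ints in 1..p
    B: int

    def __post_init__(self):
        if np.any(self.fk < 0) or np.any(self.fk > 1):
            raise DataError("bootstrap frequencies must lie in [0, 1]")
        p = self.fk.shape[1]
        if np.any(self.k0 < 1) or np.any(self.k0 > p):
            raise DataError("k0 must lie in 1..p")


@dataclasses.dataclass(frozen=True)
class DetectionResult:
    """Per-locus claims of one detection method."""

    method: str
    marker_id: tuple[str, ...]
    claimed: np.ndarray          # (L,) bool
    statistic: np.ndarray        # (L,) statistic compared to the threshold
    threshold: np.ndarray        # (L,)
    k0: np.ndarray               # (L,) selected effect count (p where n/a)
    trait_sets: tuple[tuple[int, ...], ...]  # nontrivial traits per locus

    def __post_init__(self):
        expect = self.statistic > self.threshold
        if not np.array_equal(np.asarray(self.claimed, dtype=bool), expect):
            raise DataError("claimed must equal statistic > threshold")

    @property
    def any_claim(self) -> bool:
        return bool(np.any(self.claimed))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": list(self.marker_id),
            "claimed": np.asarray(self.claimed, dtype=bool),
            "statistic": self.statistic,
            "threshold": self.threshold,
            "k0": self.k0,
            "traits": [" ".join(str(t) for t in s) for s in self.trait_sets],
        })


def select_k0(fk: np.ndarray) -> np.ndarray:
    """Effect count maximizing f_k per locus.

    Unique maximizer -> that k; ties -> the integer part of the average of
    the smallest and the largest maximizing k.
    """
    fk = np.atleast_2d(fk)
    best = fk.max(axis=1, keepdims=True)
    tie = fk >= best - 1e-12
    ks = np.arange(1, fk.shape[1] + 1)
    kmin = np.where(tie, ks, np.inf).min(axis=1)
    kmax = np.where(tie, ks, -np.inf).max(axis=1)
    return ((kmin + kmax) // 2).astype(int)


def bootstrap_best_k(geno: GenotypeMatrix, Y: PhenotypeMatrix, B: int,
                     seed: int) -> np.ndarray:
    """Best-k statistics for B paired case resamples: (B, L, p)."""
    if B < 1:
        raise DataError("bootstrap count must be positive")
    rng = np.random.default_rng(seed)
    Ym = Y.values
    N, p = Ym.shape
    L = geno.n_markers
    out = np.empty((B, L, p))
    chunk = max(1, 8192 // L)
    b = 0
    while b < B:
        m = min(chunk, B - b)
        # per-resample S differs, so stack workspaces with batched S
        Sb = np.empty((m * L, p, p))
        Wb = np.empty((m * L, p, p))
        for j in range(m):
            idx = rng.integers(0, N, size=N)
            Yb = core.center(Ym[idx])
            S = Yb.T @ Yb
            Xb = geno.values[idx]
            W = core.residual_cross_products(S, Yb, Xb)
            Sb[j * L:(j + 1) * L] = S
            Wb[j * L:(j + 1) * L] = W
        ws = core.LocusWorkspace(Sb, Wb, N)
        best, _ = ws.backward_eliminate()
        out[b:b + m] = best.reshape(m, L, p)
        b += m
    return out


def mbp_detect(geno: GenotypeMatrix, Y: PhenotypeMatrix,
               thresholds: ThresholdSet, B: int, seed: int,
               use_beta: bool | None = None,
               scan: ScanStatistics | None = None,
               ) -> tuple[DetectionResult, BootstrapFrequency]:
    """Maximum-bootstrap-power detection.

    f_k compares each bootstrap best-k statistic to lambda_k(alpha), or to
    the more stringent lambda_k(beta) when `use_beta` (default: when p > 3,
    where the marginal thresholds saturate easily).  The final claim always
    tests the original data's best-k0 statistic against lambda_k0(alpha).
    """
    p = Y.n_traits
    if thresholds.lambda_alpha.shape[0] != p:
        raise DataError("thresholds were computed for a different trait count")
    if use_beta is None:
        use_beta = p > 3
    lam_sel = thresholds.lambda_beta if use_beta else thresholds.lambda_alpha
    boot = bootstrap_best_k(geno, Y, B, seed)
    fk = (boot > lam_sel[None, None, :]).mean(axis=0)  # (L, p)
    k0 = select_k0(fk)
    if scan is None:
        scan = scan_genome(geno, Y)
    L = scan.n_loci
    stat = scan.stats[np.arange(L), k0 - 1]
    thr = thresholds.lambda_alpha[k0 - 1]
    claimed = stat > thr
    sets = tuple(scan.best_k_sets(k0))
    result = DetectionResult("mbp", tuple(geno.marker_id), claimed, stat, thr,
                             k0, sets)
    return result, BootstrapFrequency(fk, k0, B)


def all_detect(scan: ScanStatistics, thresholds: ThresholdSet) -> DetectionResult:
    """Joint test of all effects: claim when T_lp > lambda_p(alpha)."""
    stat = scan.full_model_stat
    p = scan.n_traits
    thr = np.full(scan.n_loci, thresholds.lambda_alpha[-1])
    claimed = stat > thr
    sets = tuple(tuple(range(p)) for _ in range(scan.n_loci))
    return DetectionResult("all", scan.marker_id, claimed, stat, thr,
                           np.full(scan.n_loci, p), sets)


def indv_detect(effects: EffectTestStatistics, tau_alpha: float) -> DetectionResult:
    """Claim a locus when any individual-effect statistic exceeds tau(alpha)."""
    stat = effects.indiv.max(axis=1)
    L, p = effects.indiv.shape
    thr = np.full(L, float(tau_alpha))
    claimed = stat > thr
    sets = tuple(tuple(np.flatnonzero(effects.indiv[l] > tau_alpha)) for l in range(L))
    k0 = np.array([max(len(s), 1) for s in sets])
    return DetectionResult("indv", effects.marker_id, claimed, stat, thr, k0, sets)


def seq_detect(geno: GenotypeMatrix, Y: PhenotypeMatrix,
               seq_thresholds: np.ndarray,
               scan: ScanStatistics | None = None) -> DetectionResult:
    """Sequential elimination: starting from all p effects, test the current
    joint statistic against its per-step threshold and, failing that, drop
    the least significant effect; claim at the first significant step."""
    if scan is None:
        scan = scan_genome(geno, Y)
    L, p = scan.stats.shape
    thr = np.asarray(seq_thresholds, dtype=float)
    exceeds = scan.stats > thr[None, :]
    claimed = exceeds.any(axis=1)
    # the first significant step encountered going downward from k = p
    k_stop = np.where(claimed,
                      p - np.argmax(exceeds[:, ::-1], axis=1),
                      1)
    stat = scan.stats[np.arange(L), k_stop - 1]
    used_thr = thr[k_stop - 1]
    sets = tuple(scan.best_k_sets(k_stop))
    return DetectionResult("seq", scan.marker_id, claimed, stat, used_thr,
                           k_stop, sets)


def bicdelta_detect(geno: GenotypeMatrix, Y: PhenotypeMatrix, penalty: float,
                    scan: ScanStatistics | None = None) -> DetectionResult:
    """Model choice along the backward-elimination path with penalty per effect.

    Among the nested models with k = 0, 1, ..., p effects (the empty model
    and the best-k models of the elimination path), select the one
    minimizing the penalized criterion -T_k + k * penalty.  The locus is
    claimed when the selected model is non-empty, i.e. when T_k > k *
    penalty for some k; the retained set is that model's surviving traits.
    """
    if penalty <= 0:
        warnings.warn("non-positive penalty: every polymorphic locus will be claimed")
    if scan is None:
        scan = scan_genome(geno, Y)
    L, p = scan.stats.shape
    ks = np.arange(1, p + 1)
    gain = scan.stats - ks[None, :] * penalty  # criterion gain over the empty model
    k_best = np.argmax(gain, axis=1) + 1
    best_gain = gain[np.arange(L), k_best - 1]
    claimed = best_gain > 0
    # claimed is exactly statistic > threshold with the statistic on the
    # scale of the selected model's joint LRT
    stat = scan.stats[np.arange(L), k_best - 1]
    thr = k_best * penalty
    sets = []
    for l in range(L):
        if claimed[l]:
            sets.append(tuple(sorted(scan.elimination_order[l, p - k_best[l]:])))
        else:
            sets.append(())
    return DetectionResult("bicdelta", scan.marker_id, claimed, stat,
                           thr.astype(float), k_best, tuple(sets))
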