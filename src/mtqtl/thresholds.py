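"""Permutation-based genome-wide significance thresholds.

All thresholds derive from the same null-resampling scheme: whole genotype
rows (one individual's full marker vector) are permuted against the fixed
phenotype rows, which preserves both the trait correlation structure and
linkage between markers, and the permuted data are analyzed exactly like
the original data.  Empirical quantiles use the conservative order
statistic ceil((1 - a) * B).

Threshold families:

* lambda_k(alpha) — per-k genome-wide thresholds for the best-k statistics.
* lambda_k(beta)  — the same family made jointly valid across k: the
  per-family level beta is lowered until the event that every best-k
  maximum stays below its threshold has permutation probability >= 1-alpha,
  with equal per-family exceedance across k.
* tau(alpha)      — threshold for the largest individual-effect statistic
  over all loci and traits (the Indv procedure).
* Seq thresholds  — per-step thresholds for sequential elimination; the
  permuted data undergo the same elimination, and the per-step maxima are
  calibrated jointly exactly as for lambda_k(beta).
* BIC_delta penalty — the (1-alpha) quantile of the genome-wide best
  single-effect (one-step forward selection) statistic.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np

from . import core
from .io import DataError, GenotypeMatrix, PhenotypeMatrix, RunConfig


@dataclasses.dataclass(frozen=True)
class PermutationNull:
    """Per-permutation genome-wide maxima of the relevant statistics."""

    bestk_max: np.ndarray | None    # (B, p) max over loci of best-k stats
    indiv_max: np.ndarray | None    # (B,) max over loci and traits
    single_max: np.ndarray | None   # (B,) max over loci and traits, H4-type
    fixed_set_max: Mapping[str, np.ndarray]  # name -> (B,)
    n_permutations: int
    seed: int

    def require(self, field: str) -> np.ndarray:
        val = getattr(self, field)
        if val is None:
            raise DataError(f"permutation null lacks {field} records")
        return val


def _permutation_pass(geno: GenotypeMatrix, Y: PhenotypeMatrix,
                      n_permutations: int, seed: int,
                      record: Sequence[str] = ("bestk",),
                      fixed_sets: Mapping[str, Sequence[int]] | None = None,
                      ) -> PermutationNull:
    """Run genome scans on row-permuted genotypes, recording genome maxima."""
    if n_permutations < 1:
        raise DataError("n_permutations must be positive")
    rng = np.random.default_rng(seed)
    Ym = Y.values
    N, p = Ym.shape
    L = geno.n_markers
    Yc = core.center(Ym)
    S = Yc.T @ Yc
    Xc = core.center(geno.values)
    want_bestk = "bestk" in record
    want_indiv = "indiv" in record
    want_single = "single" in record
    fixed_sets = dict(fixed_sets or {})
    bestk = np.empty((n_permutations, p)) if want_bestk else None
    indiv = np.empty(n_permutations) if want_indiv else None
    single = np.empty(n_permutations) if want_single else None
    fixed = {name: np.empty(n_permutations) for name in fixed_sets}
    chunk = max(1, 8192 // L)
    b = 0
    while b < n_permutations:
        m = min(chunk, n_permutations - b)
        cols = np.empty((N, m * L))
        for j in range(m):
            perm = rng.permutation(N)
            cols[:, j * L:(j + 1) * L] = Xc[perm]
        W = core.residual_cross_products(S, Yc, cols)
        ws = core.LocusWorkspace(S, W, N)
        if want_bestk:
            best, _ = ws.backward_eliminate()
            bestk[b:b + m] = best.reshape(m, L, p).max(axis=1)
        if want_indiv:
            indiv[b:b + m] = ws.individual_stats().reshape(m, L * p).max(axis=1)
        if want_single:
            single[b:b + m] = ws.single_effect_stats().reshape(m, L * p).max(axis=1)
        for name, active in fixed_sets.items():
            t = ws.active_set_stat(np.asarray(active, dtype=int))
            fixed[name][b:b + m] = t.reshape(m, L).max(axis=1)
        b += m
    return PermutationNull(bestk, indiv, single, fixed, n_permutations, seed)


def permutation_null_bestk(geno: GenotypeMatrix, Y: PhenotypeMatrix,
                           n_permutations: int, seed: int) -> PermutationNull:
    """Permutation records of per-k genome-wide best-k maxima."""
    return _permutation_pass(geno, Y, n_permutations, seed, record=("bestk",))


def empirical_quantile(records: np.ndarray, alpha: float) -> np.ndarray:
    """The ceil((1 - alpha) * B)-th order statistic along axis 0."""
    if not 0 < alpha < 1:
        raise DataError("alpha must lie in (0, 1)")
    records = np.asarray(records, dtype=float)
    B = records.shape[0]
    j = int(np.ceil((1.0 - alpha) * B - 1e-9))
    j = min(max(j, 1), B)
    return np.sort(records, axis=0)[j - 1]


def lambda_alpha(null: PermutationNull, alpha: float) -> np.ndarray:
    """Per-k genome-wide thresholds at marginal level alpha."""
    records = null.require("bestk_max")
    if null.n_permutations < 1.0 / alpha:
        warnings.warn(
            f"{null.n_permutations} permutations resolve tail levels only down "
            f"to {1.0 / null.n_permutations:.3g}; alpha={alpha} is below that",
            stacklevel=2)
    return empirical_quantile(records, alpha)


def lambda_beta(null: PermutationNull, alpha: float) -> tuple[np.ndarray, float]:
    """Jointly calibrated per-k thresholds and the solved per-family level.

    Finds the largest per-family level beta (equal across k) such that the
    permutation probability of every best-k genome maximum lying below its
    (1 - beta) quantile is at least 1 - alpha.  Because the thresholds are
    order statistics, the search runs over the integer order index.
    """
    if not 0 < alpha < 1:
        raise DataError("alpha must lie in (0, 1)")
    records = null.require("bestk_max")
    B = records.shape[0]
    sorted_rec = np.sort(records, axis=0)

    def coverage(j: int) -> float:
        lam = sorted_rec[j - 1]
        return float(np.mean(np.all(records <= lam, axis=1)))

    lo = int(np.ceil((1.0 - alpha) * B - 1e-9))  # joint never looser than marginal
    hi = B
    if coverage(lo) >= 1.0 - alpha:
        hi = lo
    while lo < hi:
        mid = (lo + hi) // 2
        if coverage(mid) >= 1.0 - alpha:
            hi = mid
        else:
            lo = mid + 1
    j = hi
    beta = (B - j) / B if records.shape[1] > 1 else alpha
    if records.shape[1] == 1:
        j = int(np.ceil((1.0 - alpha) * B - 1e-9))
    return sorted_rec[j - 1].copy(), float(beta)


def tau_alpha_indv(geno: GenotypeMatrix, Y: PhenotypeMatrix,
                   n_permutations: int, alpha: float, seed: int) -> float:
    """Threshold for the Indv procedure: max over loci and traits of the
    individual-effect statistics on permuted data."""
    null = _permutation_pass(geno, Y, n_permutations, seed, record=("indiv",))
    return float(empirical_quantile(null.require("indiv_max"), alpha))


def seq_thresholds(geno: GenotypeMatrix, Y: PhenotypeMatrix,
                   n_permutations: int, alpha: float, seed: int) -> np.ndarray:
    """Per-step thresholds for sequential elimination, jointly at level alpha.

    Permuted data are subjected to the same least-significant-effect
    removal as real data; the per-step genome maxima coincide with the
    best-k records, and the joint calibration equalizes exceedance across
    steps.
    """
    null = _permutation_pass(geno, Y, n_permutations, seed, record=("bestk",))
    thr, _ = lambda_beta(null, alpha)
    return thr


def bic_delta_penalty(geno: GenotypeMatrix, Y: PhenotypeMatrix,
                      n_permutations: int, alpha: float, seed: int) -> float:
    """Penalty from the permutation null of one-step forward selection."""
    null = _permutation_pass(geno, Y, n_permutations, seed, record=("single",))
    return float(empirical_quantile(null.require("single_max"), alpha))


@dataclasses.dataclass(frozen=True)
class ThresholdSet:
    """All threshold families for one (genotype, phenotype) configuration."""

    lambda_alpha: np.ndarray        # (p,)
    lambda_beta: np.ndarray         # (p,)
    beta: float
    tau_alpha: float
    seq_thresholds: np.ndarray      # (p,)
    bic_penalty: float
    zeta: Mapping[str, float]       # named fixed-set thresholds
    alpha: float
    n_permutations: int
    seed: int

    def __post_init__(self):
        if np.any(self.lambda_alpha < 0) or np.any(self.lambda_beta < 0):
            raise DataError("thresholds must be non-negative")
        if np.any(self.lambda_beta + 1e-9 < self.lambda_alpha):
            raise DataError("jointly adjusted thresholds cannot be looser")

    def to_dict(self) -> dict:
        return {
            "lambda_alpha": list(map(float, self.lambda_alpha)),
            "lambda_beta": list(map(float, self.lambda_beta)),
            "beta": self.beta,
            "tau_alpha": self.tau_alpha,
            "seq_thresholds": list(map(float, self.seq_thresholds)),
            "bic_penalty": self.bic_penalty,
            "zeta": {k: float(v) for k, v in self.zeta.items()},
            "provenance": {"alpha": self.alpha,
                           "n_permutations": self.n_permutations,
                           "seed": self.seed},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdSet":
        prov = d["provenance"]
        return cls(np.asarray(d["lambda_alpha"]), np.asarray(d["lambda_beta"]),
                   float(d["beta"]), float(d["tau_alpha"]),
                   np.asarray(d["seq_thresholds"]), float(d["bic_penalty"]),
                   dict(d.get("zeta", {})), float(prov["alpha"]),
                   int(prov["n_permutations"]), int(prov["seed"]))


def estimate_thresholds(geno: GenotypeMatrix, Y: PhenotypeMatrix,
                        config: RunConfig,
                        fixed_sets: Mapping[str, Sequence[int]] | None = None,
                        ) -> ThresholdSet:
    """One permutation pass producing every threshold family.

    `fixed_sets` optionally names trait subsets whose fixed-set genome-wide
    thresholds zeta(alpha) are recorded in the same pass (used by the
    known-nonzero-set oracle mode of the power studies).
    """
    null = _permutation_pass(geno, Y, config.n_permutations, config.seed,
                             record=("bestk", "indiv", "single"),
                             fixed_sets=fixed_sets)
    lam_a = lambda_alpha(null, config.alpha)
    lam_b, beta = lambda_beta(null, config.alpha)
    tau = float(empirical_quantile(null.require("indiv_max"), config.alpha))
    penalty = float(empirical_quantile(null.require("single_max"), config.alpha))
    zeta = {name: float(empirical_quantile(rec, config.alpha))
            for name, rec in null.fixed_set_max.items()}
    return ThresholdSet(lam_a, lam_b, beta, tau, lam_b.copy(), penalty, zeta,
                        config.alpha, config.n_permutations, config.seed)
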