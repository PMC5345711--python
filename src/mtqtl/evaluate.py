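"""Monte-Carlo study drivers and jackknife relative-frequency evaluation.

`type1_error_study` and `power_study` rerun the full pipeline — phenotype
generation, permutation threshold estimation, detection — independently in
every replicate, mirroring how the methods would be applied to real data.
`jackknife_frequency` evaluates one observed data set by delete-1
resampling: the relative frequency with which a locus is re-claimed across
subsamples is a surrogate for (not an estimate of) statistical power.

The reduced "desk" profile (N=100 individuals, p=8 traits, L=30 markers on
five chromosomes, 300 permutations, 100 bootstraps, 100 replicates) keeps
a full calibration study within minutes while leaving binomial confidence
intervals informative.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import core
from .assoc import association_matrix, two_step
from .detect import (DetectionResult, all_detect, bicdelta_detect, indv_detect,
                     mbp_detect, seq_detect)
from .io import (DataError, GeneticMap, GenotypeMatrix, PhenotypeMatrix,
                 RunConfig, VALID_METHODS)
from .mtreg import effect_tests, scan_genome
from .simulate import (QTLEffectSpec, desk_map, make_paper_like_spec, null_spec,
                       simulate_ril_genotypes, simulate_traits)
from .thresholds import ThresholdSet, estimate_thresholds


def binomial_se(p_hat: float | np.ndarray, n: int) -> float | np.ndarray:
    """SE of a proportion estimated from n independent replicates."""
    return np.sqrt(np.asarray(p_hat) * (1.0 - np.asarray(p_hat)) / n)


@dataclasses.dataclass(frozen=True)
class StudyTable:
    """Per-method estimates with binomial standard errors."""

    frame: pd.DataFrame  # columns: method, estimate, se
    nsim: int

    def estimate(self, method: str) -> float:
        return float(self.frame.set_index("method").loc[method, "estimate"])


@dataclasses.dataclass(frozen=True)
class ResamplingSummary:
    """Delete-1 jackknife relative frequencies for one data set."""

    method: str
    marker_id: tuple[str, ...]
    p_hat_l: np.ndarray        # (L,) zeroed below the cutoff
    p_hat_l_raw: np.ndarray    # (L,) before zeroing
    p_hat: float               # fraction of subsamples with any claim
    scheme: str
    B: int
    zeroing_cutoff: float


def _child_seeds(seed: int, n: int) -> list[int]:
    """Independent sub-seeds below 2**31 derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_detector(method: str, geno: GenotypeMatrix, Y: PhenotypeMatrix,
                 thresholds: ThresholdSet, config: RunConfig, seed: int,
                 scan=None, effects=None) -> DetectionResult:
    """Dispatch one detection method on one data set."""
    if method == "all":
        return all_detect(scan if scan is not None else scan_genome(geno, Y),
                          thresholds)
    if method == "mbp":
        result, _ = mbp_detect(geno, Y, thresholds, config.n_bootstrap, seed,
                               scan=scan)
        return result
    if method == "indv":
        eff = effects if effects is not None else effect_tests(geno, Y)
        return indv_detect(eff, thresholds.tau_alpha)
    if method == "seq":
        return seq_detect(geno, Y, thresholds.seq_thresholds, scan=scan)
    if method == "bicdelta":
        return bicdelta_detect(geno, Y, thresholds.bic_penalty, scan=scan)
    raise DataError(f"unknown method {method!r}")


def type1_error_study(geno: GenotypeMatrix, spec: QTLEffectSpec,
                      methods: Sequence[str], nsim: int,
                      config: RunConfig) -> StudyTable:
    """Genome-wide false-positive rate of each method under a no-QTL spec.

    Each replicate draws fresh phenotypes, re-estimates every threshold by
    permutation, and records whether any locus is claimed.
    """
    if not spec.is_null():
        raise DataError("type-I-error study requires a spec without QTL effects")
    seeds = _child_seeds(config.seed, 3 * nsim)
    claims = {m: np.zeros(nsim, dtype=bool) for m in methods}
    for i in range(nsim):
        s_pheno, s_perm, s_det = seeds[3 * i:3 * i + 3]
        Y = simulate_traits(geno, spec, s_pheno)
        cfg_i = dataclasses.replace(config, seed=s_perm)
        thr = estimate_thresholds(geno, Y, cfg_i)
        scan = scan_genome(geno, Y)
        effects = effect_tests(geno, Y) if "indv" in methods else None
        for m in methods:
            res = run_detector(m, geno, Y, thr, config, s_det, scan=scan,
                               effects=effects)
            claims[m][i] = res.any_claim
    rows = [(m, claims[m].mean(), float(binomial_se(claims[m].mean(), nsim)))
            for m in methods]
    return StudyTable(pd.DataFrame(rows, columns=["method", "estimate", "se"]),
                      nsim)


@dataclasses.dataclass(frozen=True)
class PowerStudyResult:
    """Per-locus claim rates, and MBP effect-count selections, over replicates."""

    rates: pd.DataFrame           # index marker, one column per method/mode
    k0_samples: np.ndarray | None  # (nsim, L) MBP-selected counts
    assoc_rates: pd.DataFrame | None  # locus x trait true-association rates
    nsim: int


def power_study(geno: GenotypeMatrix, spec: QTLEffectSpec,
                methods: Sequence[str], nsim: int, config: RunConfig,
                fixed_k: Sequence[int] | None = None,
                include_nze: bool = False,
                track_assoc: Sequence[str] = ()) -> PowerStudyResult:
    """Per-locus detection rates under a spec with QTL.

    Besides the named methods, `fixed_k` adds modes that test exactly the
    best k effects against lambda_k(alpha), and `include_nze` adds the
    known-nonzero-set oracle: at each simulated QTL the statistic for
    exactly the true nonzero traits, against that fixed set's own
    genome-wide permutation threshold.  `track_assoc` lists methods for
    which the per-(locus, trait) association rate of the method+idv
    two-step procedure is also recorded.
    """
    if spec.is_null():
        raise DataError("power study requires at least one QTL effect")
    p = spec.n_traits
    L = geno.n_markers
    fixed_k = list(fixed_k or [])
    if any(k < 1 or k > p for k in fixed_k):
        raise DataError("fixed_k entries must lie in 1..p")
    qtl_idx = {m: geno.marker_id.index(m) for m in spec.qtl_loci}
    true_sets = {m: tuple(np.flatnonzero(g)) for m, g in zip(spec.qtl_loci, spec.gamma)
                 if np.any(g)}
    fixed_sets = {m: list(s) for m, s in true_sets.items()} if include_nze else None
    cols = list(methods) + [f"bestk{k}" for k in fixed_k] + (
        ["nze"] if include_nze else [])
    counts = {c: np.zeros(L) for c in cols}
    k0_samples = np.zeros((nsim, L), dtype=int) if "mbp" in methods else None
    assoc_counts = {m: np.zeros((L, p)) for m in track_assoc}
    seeds = _child_seeds(config.seed, 3 * nsim)
    for i in range(nsim):
        s_pheno, s_perm, s_det = seeds[3 * i:3 * i + 3]
        Y = simulate_traits(geno, spec, s_pheno)
        cfg_i = dataclasses.replace(config, seed=s_perm)
        thr = estimate_thresholds(geno, Y, cfg_i, fixed_sets=fixed_sets)
        scan = scan_genome(geno, Y)
        effects = effect_tests(geno, Y) if "indv" in methods else None
        for m in methods:
            if m == "mbp":
                res, bf = mbp_detect(geno, Y, thr, config.n_bootstrap, s_det,
                                     scan=scan)
                k0_samples[i] = bf.k0
            else:
                res = run_detector(m, geno, Y, thr, config, s_det, scan=scan,
                                   effects=effects)
            counts[m] += res.claimed
            if m in assoc_counts:
                assoc = two_step(res, geno, Y, config.alpha)
                assoc_counts[m] += association_matrix(assoc, geno.marker_id,
                                                      Y.trait_names)
        for k in fixed_k:
            counts[f"bestk{k}"] += scan.stats[:, k - 1] > thr.lambda_alpha[k - 1]
        if include_nze:
            ws = core.workspace_for_loci(Y.values, geno.values)
            for m, s in true_sets.items():
                l = qtl_idx[m]
                t = ws.active_set_stat(np.asarray(s, dtype=int))[l]
                counts["nze"][l] += t > thr.zeta[m]
    rates = pd.DataFrame({c: counts[c] / nsim for c in cols},
                         index=list(geno.marker_id))
    rates.index.name = "marker"
    assoc_rates = None
    if track_assoc:
        frames = {}
        for m in track_assoc:
            df = pd.DataFrame(assoc_counts[m] / nsim, index=list(geno.marker_id))
            frames[m] = df
        assoc_rates = pd.concat(frames, axis=1)
    return PowerStudyResult(rates, k0_samples, assoc_rates, nsim)


def jackknife_frequency(geno: GenotypeMatrix, Y: PhenotypeMatrix, method: str,
                        thresholds: ThresholdSet, config: RunConfig,
                        zeroing_cutoff: float | None = None) -> ResamplingSummary:
    """Delete-1 jackknife relative frequencies p_hat_l and p_hat.

    Each of the N subsamples drops one individual and reruns the detector
    with the thresholds precomputed on the full data; per-locus relative
    frequencies below the zeroing cutoff are reported as zero.
    """
    if method not in VALID_METHODS:
        raise DataError(f"unknown method {method!r}")
    N = Y.n_individuals
    p = Y.n_traits
    if N - 1 <= p + 2:
        raise DataError("sample too small for delete-1 refits")
    cutoff = config.zeroing_cutoff if zeroing_cutoff is None else zeroing_cutoff
    L = geno.n_markers
    claims = np.zeros((N, L), dtype=bool)
    seeds = _child_seeds(config.seed, N)
    for b in range(N):
        keep = np.r_[0:b, b + 1:N]
        geno_b = GenotypeMatrix(geno.values[keep],
                                tuple(geno.individuals[i] for i in keep),
                                geno.marker_id)
        Y_b = PhenotypeMatrix(Y.values[keep], Y.trait_names,
                              tuple(Y.individuals[i] for i in keep))
        res = run_detector(method, geno_b, Y_b, thresholds, config, seeds[b])
        claims[b] = res.claimed
    p_hat_l_raw = claims.mean(axis=0)
    p_hat = float(claims.any(axis=1).mean())
    p_hat_l = np.where(p_hat_l_raw < cutoff, 0.0, p_hat_l_raw)
    return ResamplingSummary(method, tuple(geno.marker_id), p_hat_l,
                             p_hat_l_raw, p_hat, "delete-1 jackknife", N, cutoff)


# --------------------------------------------------------------------------
# Reduced-scale study profile


def desk_config(seed: int = 0, **overrides) -> RunConfig:
    """RunConfig for the reduced-scale profile (300 permutations, 100 bootstraps)."""
    kw = dict(alpha=0.05, n_permutations=300, n_bootstrap=100, seed=seed)
    kw.update(overrides)
    return RunConfig(**kw)


def desk_scenario(kind: str, seed: int = 0,
                  n_individuals: int = 100, p: int = 8
                  ) -> tuple[GeneticMap, GenotypeMatrix, QTLEffectSpec]:
    """Prebuilt reduced-scale scenarios.

    Per-trait heritabilities are calibrated so detection power at the
    profile's N = 100 is mid-range — large enough that method differences
    are visible over ~100 replicates, small enough that no method
    saturates (the same calibration principle used for the full-scale
    transcript-based settings, which have more individuals and hence
    smaller per-trait effects).

    kind:
      'null'      — no QTL anywhere (type-I-error calibration).
      'sparse'    — one QTL affecting a single trait (h2 = 8%), the extreme
                    few-effects-among-many configuration.
      'moderate'  — one QTL affecting three of the eight traits (h2 = 5%
                    each), used for effect-count selection behaviour.
      'multi'     — five QTL, one per chromosome, with 1, 6, 8, 2 and 4
                    nonzero effects of random sign, per-QTL heritabilities
                    stepping down geometrically from 8% to 2% so the
                    sparsest QTL carry the strongest per-trait
                    contributions.
    """
    gmap = desk_map()
    geno = simulate_ril_genotypes(gmap, n_individuals, seed=seed + 1)
    if kind == "null":
        spec = null_spec(p)
    elif kind == "sparse":
        spec = make_paper_like_spec(p, [1], gmap, target_h2_range=(0.08, 0.08),
                                    seed=seed)
    elif kind == "moderate":
        spec = make_paper_like_spec(p, [3], gmap, target_h2_range=(0.05, 0.05),
                                    seed=seed)
    elif kind == "multi":
        spec = make_paper_like_spec(p, [1, 6, 8, 2, 4], gmap,
                                    target_h2_range=(0.02, 0.08),
                                    random_signs=True, seed=seed)
    else:
        raise DataError(f"unknown scenario {kind!r}")
    return gmap, geno, spec
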