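"""Synthetic RIL genotypes and multivariate-normal traits.

The genotype generator emulates a biparental recombinant-inbred-line (RIL)
population produced by repeated selfing: along a chromosome, genotypes form
a two-state Markov chain whose switch probability between adjacent markers
at map distance d cM is the RIL recombination frequency

    R = 2 r / (1 + 2 r),    r = (1 - exp(-2 d / 100)) / 2   (Haldane),

chromosomes segregating independently.  Traits follow the single-QTL-per
-locus multivariate model: row i of the phenotype matrix is

    y_i = beta0 + sum_l x_il * gamma_l + eps_i,   eps_i ~ N_p(0, Sigma),

with x coded +-0.5.  Under balanced alleles Var(x) = 1/4, so a nonzero
effect gamma on a trait with residual variance sigma_kk explains a fraction
h2 = (gamma^2/4) / (gamma^2/4 + sigma_kk) of that trait's variance; effect
magnitudes in `make_paper_like_spec` are solved from this identity.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .io import DataError, GeneticMap, GenotypeMatrix, PhenotypeMatrix


def haldane_recomb(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Meiotic recombination fraction r for a map distance in cM (Haldane)."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


def ril_selfing_recomb(r: np.ndarray | float) -> np.ndarray | float:
    """RIL-by-selfing recombination frequency R = 2r / (1 + 2r)."""
    r = np.asarray(r, dtype=float)
    return 2.0 * r / (1.0 + 2.0 * r)


@dataclasses.dataclass(frozen=True)
class QTLEffectSpec:
    """Trait-generation parameters: intercepts, QTL effects, residual covariance."""

    beta0: np.ndarray               # (p,)
    qtl_loci: tuple[str, ...]       # marker ids carrying effects
    gamma: np.ndarray               # (n_qtl, p)
    sigma: np.ndarray               # (p, p) positive definite

    def __post_init__(self):
        beta0 = np.atleast_1d(np.asarray(self.beta0, dtype=float))
        gamma = np.asarray(self.gamma, dtype=float)
        sigma = np.asarray(self.sigma, dtype=float)
        if gamma.size == 0:
            gamma = gamma.reshape(0, beta0.size)
        object.__setattr__(self, "beta0", beta0)
        object.__setattr__(self, "gamma", gamma)
        object.__setattr__(self, "sigma", sigma)
        p = beta0.size
        if sigma.shape != (p, p):
            raise DataError("sigma must be p x p")
        if not np.allclose(sigma, sigma.T):
            raise DataError("sigma must be symmetric")
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise DataError("sigma must be positive definite")
        if gamma.shape != (len(self.qtl_loci), p):
            raise DataError("gamma must be (#qtl) x p")

    @property
    def n_traits(self) -> int:
        return self.beta0.size

    @property
    def nonzero_counts(self) -> np.ndarray:
        """Number of nonzero effects per QTL."""
        return (self.gamma != 0).sum(axis=1)

    def is_null(self) -> bool:
        return self.gamma.size == 0 or not np.any(self.gamma)


def simulate_ril_genotypes(gmap: GeneticMap, n: int, seed: int) -> GenotypeMatrix:
    """Draw n RIL genotype rows on the given map.

    The first marker of each chromosome is a fair draw between the two
    parental classes; subsequent markers switch class with the RIL-by-
    selfing recombination frequency for the adjacent map distance.
    """
    if n < 2:
        raise DataError("need at least 2 individuals")
    rng = np.random.default_rng(seed)
    L = gmap.n_markers
    values = np.empty((n, L))
    for chrom in gmap.chromosomes:
        idx = gmap.chromosome_index(chrom)
        d = np.diff(gmap.position[idx])
        R = ril_selfing_recomb(haldane_recomb(d))
        state = rng.random(n) < 0.5
        values[:, idx[0]] = np.where(state, 0.5, -0.5)
        for j, rr in enumerate(R):
            flip = rng.random(n) < rr
            state = state ^ flip
            values[:, idx[j + 1]] = np.where(state, 0.5, -0.5)
    labels = tuple(f"ril{i + 1}" for i in range(n))
    return GenotypeMatrix(values, labels, tuple(gmap.marker_id))


def truncate_and_scale_effects(beta_hat: np.ndarray, sigma_hat: np.ndarray,
                               ratio_cutoff: float = 0.45,
                               scale: float = 1.0 / 3.0,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Zero out small fitted effects and shrink the rest.

    gamma_lk = scale * beta_hat_lk when |beta_hat_lk| / sqrt(sigma_hat_kk)
    >= ratio_cutoff, else 0.  The standardization divides by the residual
    standard deviation of the trait.  Returns (gamma, per-QTL nonzero counts).
    """
    beta_hat = np.atleast_2d(np.asarray(beta_hat, dtype=float))
    diag = np.diag(np.asarray(sigma_hat, dtype=float))
    if np.any(diag <= 0) or not np.all(np.isfinite(diag)):
        raise DataError("sigma_hat must have positive diagonal")
    sd = np.sqrt(diag)
    keep = np.abs(beta_hat) / sd >= ratio_cutoff
    gamma = np.where(keep, beta_hat * scale, 0.0)
    return gamma, keep.sum(axis=1)


def simulate_traits(geno: GenotypeMatrix, spec: QTLEffectSpec, seed: int,
                    trait_names: Sequence[str] | None = None) -> PhenotypeMatrix:
    """Draw one phenotype matrix for the given genotypes under the spec."""
    p = spec.n_traits
    missing = [m for m in spec.qtl_loci if m not in geno.marker_id]
    if missing:
        raise DataError(f"spec loci absent from genotypes: {missing}")
    rng = np.random.default_rng(seed)
    n = geno.n_individuals
    mean = np.tile(spec.beta0, (n, 1))
    for locus, g in zip(spec.qtl_loci, spec.gamma):
        col = geno.values[:, geno.marker_id.index(locus)]
        mean += np.outer(col, g)
    chol = np.linalg.cholesky(spec.sigma)
    eps = rng.standard_normal((n, p)) @ chol.T
    names = tuple(trait_names) if trait_names else tuple(f"T{k + 1}" for k in range(p))
    return PhenotypeMatrix(mean + eps, names, tuple(geno.individuals))


def exchangeable_sigma(p: int, rho: float, variances: np.ndarray | None = None
                       ) -> np.ndarray:
    """Covariance with a common pairwise correlation rho."""
    v = np.ones(p) if variances is None else np.asarray(variances, dtype=float)
    sd = np.sqrt(v)
    sigma = rho * np.outer(sd, sd)
    np.fill_diagonal(sigma, v)
    return sigma


def one_factor_sigma(p: int, seed: int, loading_range: tuple[float, float] = (0.15, 0.95)
                     ) -> np.ndarray:
    """Unit-variance covariance from a single latent factor.

    Loadings drawn uniformly give pairwise correlations spanning roughly
    loading_range[0]**2 .. loading_range[1]**2, mimicking the wide spread
    of correlations among transcript traits.
    """
    rng = np.random.default_rng(seed)
    lam = rng.uniform(*loading_range, size=p)
    sigma = np.outer(lam, lam)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def gamma_for_h2(h2: np.ndarray | float, sigma_kk: np.ndarray | float) -> np.ndarray:
    """Effect magnitude explaining fraction h2 of trait variance (x coded +-0.5)."""
    h2 = np.asarray(h2, dtype=float)
    return 2.0 * np.sqrt(np.asarray(sigma_kk, dtype=float) * h2 / (1.0 - h2))


def make_paper_like_spec(p: int, nze_counts: Sequence[int],
                         gmap: GeneticMap,
                         target_h2_range: tuple[float, float] = (0.002, 0.059),
                         correlation_model: str = "exchangeable",
                         rho: float = 0.66,
                         sigma: np.ndarray | None = None,
                         qtl_loci: Sequence[str] | None = None,
                         h2_per_qtl: Sequence[float] | None = None,
                         random_signs: bool = False,
                         seed: int = 0) -> QTLEffectSpec:
    """Build an effect spec with a prescribed nonzero pattern.

    One QTL per entry of `nze_counts`; by default QTL q sits at the middle
    marker of chromosome q (cycling).  Per-QTL heritabilities are geometric
    steps from the high to the low end of `target_h2_range`, equal across
    that QTL's nonzero traits, so the strongest per-trait contributions go
    with the sparsest QTL.  Signs are positive unless `random_signs`, which
    flips each nonzero entry independently.
    """
    lo, hi = target_h2_range
    if not (0 <= lo <= hi < 1):
        raise DataError("infeasible h2 range")
    if any(c > p or c < 0 for c in nze_counts):
        raise DataError("each nonzero count must lie in [0, p]")
    rng = np.random.default_rng(seed)
    nq = len(nze_counts)
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)
    elif correlation_model == "exchangeable":
        sigma = exchangeable_sigma(p, rho)
    elif correlation_model == "factor":
        sigma = one_factor_sigma(p, seed=seed)
    else:
        raise DataError("correlation_model must be 'exchangeable' or 'factor'")
    if qtl_loci is None:
        chroms = gmap.chromosomes
        qtl_loci = []
        for q in range(nq):
            idx = gmap.chromosome_index(chroms[q % len(chroms)])
            qtl_loci.append(gmap.marker_id[idx[len(idx) // 2]])
    if h2_per_qtl is None:
        if nq == 1 or hi == lo:
            h2_per_qtl = np.full(nq, hi)
        else:
            h2_per_qtl = np.geomspace(hi, max(lo, 1e-6), nq)
    gamma = np.zeros((nq, p))
    diag = np.diag(sigma)
    for q, count in enumerate(nze_counts):
        if count == 0:
            continue
        traits = rng.choice(p, size=count, replace=False)
        g = gamma_for_h2(h2_per_qtl[q], diag[traits])
        if random_signs:
            g = g * rng.choice([1.0, -1.0], size=count)
        gamma[q, traits] = g
    return QTLEffectSpec(np.zeros(p), tuple(qtl_loci), gamma, sigma)


def null_spec(p: int, sigma: np.ndarray | None = None, rho: float = 0.66
              ) -> QTLEffectSpec:
    """A no-QTL spec (type-I-error scenarios)."""
    if sigma is None:
        sigma = exchangeable_sigma(p, rho)
    return QTLEffectSpec(np.zeros(p), (), np.zeros((0, p)), sigma)


def desk_map(markers_per_chrom: int = 6, n_chrom: int = 5,
             spacing_cm: float = 5.0) -> GeneticMap:
    """Small evenly spaced map used by the reduced-scale study profile."""
    ids, chroms, pos = [], [], []
    k = 0
    for c in range(n_chrom):
        for j in range(markers_per_chrom):
            k += 1
            ids.append(f"m{k}")
            chroms.append(f"chr{c + 1}")
            pos.append(j * spacing_cm)
    return GeneticMap(tuple(ids), tuple(chroms), np.array(pos))


def paper_like_map(seed: int = 0) -> GeneticMap:
    """Synthetic 95-marker map on five chromosomes.

    Emulates the summary geometry of the Bay-0 x Sha RIL marker map
    (95 markers, five chromosomes, adjacent spacings between about 2.2 and
    10.9 cM with median near 4.8); the marker coordinates themselves are
    synthetic draws, not the published map.
    """
    rng = np.random.default_rng(seed)
    ids, chroms, pos = [], [], []
    counts = [20, 20, 19, 18, 18]  # 95 markers total
    k = 0
    for c, cnt in enumerate(counts):
        gaps = rng.triangular(2.224, 4.771, 10.944, size=cnt - 1)
        p = np.concatenate([[0.0], np.cumsum(gaps)])
        for x in p:
            k += 1
            ids.append(f"m{k}")
            chroms.append(f"chr{c + 1}")
            pos.append(round(float(x), 3))
    return GeneticMap(tuple(ids), tuple(chroms), np.array(pos))
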