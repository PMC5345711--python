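# Methods

## Model and test statistics

At a scanning locus the traits follow a multivariate-normal single-QTL
regression: trait *k* of individual *n* is `y_nk = β_0k + x_nl β_lk +
ε_nk` with genotype code `x ∈ {±1/2}` and residual vector `ε_n ~ N_p(0,
Σ)`, rows independent. Scans test marker positions only; mixture-model
interval mapping between markers, covariates and kinship corrections are
out of scope.

All tests are likelihood-ratio statistics `T = N · ln(det Σ̂₀ / det Σ̂₁)`
with maximum-likelihood (divide-by-N) covariance estimates, i.e. exactly
−2× the log-likelihood difference of the nested fits; REML-style
estimates are not used. For a model with genotype effects on a trait
subset K only, the constrained MLE has a closed form obtained by factoring
the joint density into the marginal law of the unaffected traits
(intercept-only regression) and the conditional law of the affected traits
given them (unrestricted regression on intercept, genotype and the
unaffected traits). Writing S for the centered trait cross-product matrix
and W for the residual cross-product after regressing every trait on the
genotype,

    N · ln det Σ̂(K) = ln det S[K̄] + ln det W − ln det W[K̄]   (K̄ = complement),

so every statistic in the package reduces to submatrix log-determinants of
two p×p matrices per locus. This identity was verified to machine
precision against an iterated-FGLS fit of the stacked constrained system,
and the test suite keeps that cross-check. A corollary worth knowing: the
"effect k given all other effects" statistic collapses algebraically to
the marginal single-trait LRT of trait k; the "effect k alone, others
excluded" statistic does not.

Backward elimination at each locus repeatedly removes the effect whose
removal reduces the joint statistic least, producing the nested best-k
statistics `T_l1 ≤ … ≤ T_lp` and an elimination order. Equal candidate
scores resolve to the lowest trait index; a cumulative-maximum guard
enforces nestedness against float jitter. Monomorphic genotype columns
(possible in bootstrap or jackknife resamples) score 0 for every statistic
rather than raising, so resampling loops never abort; direct single-locus
calls additionally warn.

Determinants of principal submatrices are evaluated in bulk across loci ×
permutations × bootstrap resamples, using closed forms up to order 4 and
Jacobi's complementary-minor identity `det S[A] = det S · det(S⁻¹[Aᶜ])` so
the working order never exceeds p/2. This is what makes re-estimating
thresholds inside every Monte-Carlo replicate affordable.

## Thresholds

Permutations shuffle whole genotype rows against fixed phenotype rows,
preserving both the trait covariance and inter-marker linkage. Empirical
quantiles use the conservative order statistic `⌈(1−α)B⌉` (with a 1e−9
slack against float roundoff), making published runs bit-reproducible
from the seed.

* `λ_k(α)`: per-k quantile of the genome-wide best-k maxima.
* `λ_k(β)`: the per-family level β is solved by bisection over the integer
  order index — the resolution limit of a B-permutation sample — until the
  joint event "every best-k maximum below its threshold" has empirical
  probability ≥ 1−α, with equal per-family exceedance across k. For p=1
  this reduces to `λ_1(α)`; for independent families it approaches the
  Šidák level `1−(1−α)^{1/p}` (a frozen test checks this on synthetic
  records).
* `τ(α)` (Indv): quantile of the max over loci and traits of the
  individual-effect statistics.
* Seq: permuted data undergo the same sequential elimination as real data;
  the per-step genome maxima coincide with the best-k records, and the
  per-step thresholds are the jointly equalized `λ_k(β)` family. Many
  admissible Seq threshold schemes exist; this equalized-joint choice
  mirrors the equal-probability constraint used for `λ_k(β)`.
* BIC_δ penalty: quantile of the genome-wide best single-effect statistic
  under one-step forward selection on permuted data.

## Detection procedures

* **All** claims a locus when `T_lp > λ_p(α)` (strict inequality
  everywhere; a statistic equal to its threshold is never a claim).
* **MBP** draws B paired case resamples of the individuals, computes each
  resample's best-k statistics, forms exceedance frequencies `f_k` against
  `λ_k(α)` — or `λ_k(β)` when `use_beta`, the default for p > 3 where the
  marginal thresholds saturate (`f_k` hits 1) easily — selects `k0 =
  argmax f_k` with ties resolved to the integer part of the mean of the
  smallest and largest maximizer, and claims when the original data's
  `T_{lk0} > λ_{k0}(α)`. The final comparison deliberately uses the
  α-level threshold family even when `f_k` used the β-level one.
* **Indv** claims when any individual-effect statistic exceeds τ(α); the
  exceeding traits are the claimed associations directly, no follow-up
  needed.
* **Seq** walks the elimination path from the full model downward and
  claims at the first step whose statistic exceeds its per-step threshold.
* **BIC_δ** selects, among the empty model and the best-k models of the
  elimination path, the minimizer of `−T_k + k·δ`; the locus is claimed
  when the selected model is non-empty (equivalently `T_k > k·δ` for some
  k). An earlier stepwise-stopping variant (stop at the first elimination
  drop exceeding δ) proved anti-conservative — conditional drops high on
  the path easily exceed a penalty calibrated on single-effect forward
  statistics — and was replaced by this criterion form, which calibrates
  correctly.

## Association testing (idv)

At a claimed locus with nontrivial set of size k0, each nontrivial effect
is tested given the other nontrivial effects (the trivial set held at
zero; one constrained coefficient, hence ν = 1) against
`χ²₁(1 − α/k0)` — Bonferroni within the locus only, α respent per claimed
locus, no across-locus FDR. Trivial traits are excluded from testing and
reported non-significant by construction, so two-step association claims
are always a subset of (claimed loci) × (nontrivial traits) and inherit
the detector's familywise QTL error control.

## Synthetic data

RIL genotypes form a two-state Markov chain along each chromosome: fair
Bernoulli start, switch probability `R = 2r/(1+2r)` with Haldane
`r = (1−e^{−2d/100})/2` for adjacent map distance d cM (the map function is
a documented choice; Kosambi could be swapped in), chromosomes
independent, lines fully inbred. Traits are drawn from the model above via
a Cholesky factor, so fixed seeds reproduce data bit-exactly.

Effect construction mirrors the transcript-data recipe: a fitted effect
matrix can be truncated and scaled (`γ_lk = scale·β̂_lk` when
`|β̂_lk|/√σ̂_kk ≥ cutoff`, else 0; defaults 0.45 and 1/3, with 1/4 and 1/2
variants reachable). The printed form of that rule divides by an undefined
`β̂_kk`; this implementation reads the denominator as the residual SD and
flags the ambiguity rather than silently assuming another reading. Random
sign assignment operates per entry, seeded. `make_paper_like_spec` builds
a spec from a nonzero-count pattern: Σ is exchangeable (ρ = 0.66, the
median transcript-trait correlation) or one-factor (correlations spanning
roughly 0.02–0.9, like the transcript data's 0.02–0.96); per-QTL
heritabilities step geometrically across the target range, equal within a
QTL's nonzero traits, and effect magnitudes solve
`h² = (γ²/4)/(γ²/4 + σ_kk)` (Var(x) = 1/4 under ±1/2 coding with balanced
alleles).

What the generator does not emulate: missing genotypes or phenotypes
(rejected at load, since the emulated data are complete-case),
heterozygosity, segregation distortion, non-normal residuals, and
epistasis. Calibration results on synthetic data therefore speak to the
statistical machinery, not to robustness against those features of real
data.

## Study profiles and problem sizes

The full-scale configuration (N = 211 lines, p = 16 traits, L = 95
markers, 1200 permutations, 250 bootstraps, 250 replicates) is supported
but slow. The bundled desk profile — nsim = 100, 300 permutations, 100
bootstraps, N = 100, p = 8, L = 30 on five chromosomes — was chosen so a
full calibration study completes in about a minute per study while
100-replicate binomial confidence intervals remain informative.

Desk-scenario heritabilities (sparse: one trait at 8%; moderate: three
traits at 5%; multi: five QTL with 1/6/8/2/4 nonzero effects of random
sign, per-QTL h² stepping from 8% down to 2%) were calibrated at design
time so that detection power at N = 100 is mid-range — the calibration
principle of the original settings, whose 0.2–5.9% per-trait range applies
at roughly twice the sample size. The multi scenario uses random signs
because uniformly positive effects aligned with an equicorrelated residual
structure leave the dense-QTL joint test nearly powerless, unlike the
mixed-sign effects estimated from real transcripts.

Monte-Carlo replicates re-estimate every threshold internally (faithful to
how the methods are applied); replicates derive independent sub-seeds from
one master seed and are order-invariant. Jackknife evaluation is delete-1
(B = N) with per-locus relative frequencies `p̂_l` zeroed below a 0.25
cutoff by default; `p̂` uses the genome-wide any-claim event and is a
surrogate for, not an estimate of, power.

## Known limitations

* The χ² reference in idv is asymptotic; no small-sample correction.
* BIC_δ with a fixed penalty underfits when many small effects are
  present — visible in the desk multi scenario, where it is strongest at
  the single-effect QTL and weakest at dense small-effect QTL.
* MBP's k0 overestimates the number of nonzero effects by design
  (guarding against the more damaging underfitting); it should not be
  read as an estimate of that number.
* Thresholds are conditional on the observed phenotypes; at 300
  permutations the α = 0.05 tail is resolved to about 1/300.
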