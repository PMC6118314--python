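# Methods

## Selection as a decision problem

Truncation selection above a threshold `y_c` turns the base population
`N(μ₁, σ²)` into a target: the left-truncated normal of the selected
parents, with normalizing constant `z = Pr(Y > y_c)` and mean
`μ_S = μ₁ + σ i`, where `i = φ(d)/(1−Φ(d))`, `d = (y_c−μ₁)/σ`, is the
selection intensity. Each candidate line, assumed `N(μ₂, σ²)` (equal
variance keeps the trait's heritability fixed), is scored by a divergence
from that target, and the Bayes action keeps the candidates with the
smallest *posterior expected* divergence — the average of the loss over the
joint posterior of model parameters and the candidate's predictive
distribution. Ranking on posterior-mean BVs alone (the `Std` baseline) is
the special case that ignores all of that uncertainty.

Thresholds are always pressure-specified here: `y_c` is the upper-`q`
quantile of the base population, so `z = q` exactly and `i` is a constant
of the pressure. This matches how breeders actually operate (keep the top
10% or 30%) and makes per-draw truncation contexts cheap.

## The losses

Univariate closed forms (`e = μ_S − μ₂ = S − R`, and `e = σ i (1−h²)`
under the breeder's equation `R = h²S`):

- KL: `−log z + [(μ_S−μ₂)² − (μ_S−μ₁)²]/(2σ²)`; equivalent
  `(S,R)`-form and heritability form `−log z + ½ i² h²(h²−2)`. The three
  forms are algebraic identities and are tested as such at 1e−12.
- CRPS: `−σ[c − 2φ(e/σ) − (e/σ)(2Φ(e/σ) − 1)]`. The additive constant
  `c` defaults to `1/π`; the textbook CRPS constant is `1/√π` and is
  available via `constant="standard"`. The constant shifts all candidates
  sharing `σ` equally, so rankings are unaffected by the choice.
- LinLin: the pinball loss `(α − 1[e<0]) e`, `α ∈ (0,1)`; `α = 0.5` is
  symmetric linear.

Multivariate (`P` phenotypic, `G` genotypic covariance; orthant truncation
`Y ≥ y_c`; `S = μ_S − μ₁` from the truncated-MVN mean):

- KL: `−log z + ½[(μ_S−μ₂)'P⁻¹(μ_S−μ₂) − S'P⁻¹S]` for a candidate mean
  `μ₂`; substituting the matrix breeder's equation `R = GP⁻¹S` gives the
  heritability form `−log z + ½ S'[(I−GP⁻¹)'P⁻¹(I−GP⁻¹) − P⁻¹]S`, with
  `GP⁻¹` acting as a matrix heritability. The sign of the `log z` term is
  fixed by the univariate limit.
- Energy Score: `E‖Y_o − μ_S‖ − ½E‖Y_o − Y_o'‖`, estimated from the
  predictive draw stream with the two independent copies realized as the
  two disjoint halves of the stream.
- MALF: `(‖e‖₂ + τ'e)‖e‖₂`, or L1 form `Σ|e_k| + τ'e`; the L1 form at one
  trait with `τ = 2α−1` is exactly `2×` LinLin. Positivity requires
  `‖τ‖ ≤ 1` (L2) / `max|τ_k| ≤ 1` (L1); larger `τ` (including the default
  per-component 0.9/0.7 at three traits) is allowed with a warning, since
  only the induced ranking matters for selection.

## Truncated-MVN quantities

The orthant probability uses scipy's Genz quasi-Monte-Carlo quadrature
(with a plain seeded Monte-Carlo mode as an alternative). The TMVN mean
uses the Tallis moment reduction — `E[Y] = μ + Pq/z` with
`q_k = f_k(y_{c,k}) · Pr(Y_{−k} ≥ y_{c,−k} | Y_k = y_{c,k})` — which is
exact up to the orthant quadrature and needs only `t` orthant evaluations
in dimension `t−1`; a seeded rejection sampler provides an independent
cross-check in the tests. Truncation probabilities below 1e−12 are treated
as degenerate and raise rather than returning infinities.

## Posterior machinery

**BRR** (single trait): `y = 1μ + Xβ + e`, iid `N(0, σ_β²)` prior on
`β`, scaled-inverse-χ² (df 5) priors on `σ_β²` and `σ_e²` with scales set
so the prior modes split the sample phenotypic variance 50/50 between
markers and residual, flat prior on `μ`. The `β` block is sampled exactly
using a one-time eigendecomposition of `X'X` (markers are column-centered,
so the projection `V'X'y` is constant across sweeps), making a sweep two
dense matrix–vector products.

**MTM** (t traits): `Y = 1m' + U + E`, `vec(U) ~ N(0, G ⊗ K)` with `K`
the trace-normalized genomic relationship matrix (jittered by 1e−8 on the
diagonal), iid residual rows `N(0, R)`, inverse-Wishart(df `t+3`, scale
half the sample covariance) priors on `G` and `R`. The line dimension is
whitened once by the eigenvectors of `K`; per sweep the trait dimension is
whitened by the generalized eigenbasis of `(G, R)`, so the genetic-value
update is a fully vectorized scalar shrinkage. Candidates (unphenotyped
lines) get per-draw genetic values from the conditional Gaussian given the
training lines through the relationship blocks of `K`.

The default chain profile is 10,000 retained draws after 30,000 burn-in;
tests and the bundled program runs use short profiles (a few hundred
retained draws), which is sufficient because every per-draw quantity here
is a smooth low-dimensional functional of the chain.

**Expected loss**: per retained draw, the base-population mean and
(co)variance are recomputed from that draw's intercept, marker effects (or
genetic values) and variance components over the full current population;
the pressure-threshold, `z` and `μ_S` follow; the candidate mean is that
draw's prediction. The per-candidate score is the arithmetic mean of the
per-draw losses; ties in the ranking are broken by candidate identifier so
selections are deterministic.

## The simulator

The generator emulates the benchmark recurrent-selection design:

- **Founders** — `n` fully homozygous lines at `p` unlinked biallelic
  loci, coded −1/+1, allele frequencies uniform on [0.05, 0.95]. Defaults
  `n = 500`, `p = 1000` (the benchmark design leaves these open; these are
  desk-scale values at which prediction accuracies are realistic).
- **Single-trait effects** — magnitudes iid Gamma(shape 2, scale 2). The
  gamma is one-sided; by default each effect receives an independent
  random sign (an all-positive mode exists), documented as this package's
  interpretation.
- **Pleiotropic effects** — per-locus 3-vectors from a zero-mean MVN with
  unit variances and target correlations (−0.37, 0.34, −0.02 for the trait
  pairs (1,2), (2,3), (1,3)). The drawn effect matrix is re-whitened to
  the target sample covariance and, when founder genotypes are supplied,
  calibrated against the realized genotype covariance so the
  first-generation TBV correlations equal the targets exactly — the
  design's stated first-generation correlations are treated as conditions
  to ensure, not expectations to approximate.
- **Phenotypes** — `y = TBV + e`, `e ~ N(0, σ_g²(1−h²)/h²)` with `σ_g²`
  the realized TBV variance of the founder generation. The residual
  variance is calibrated once and held fixed, so realized h² drifts down
  as selection erodes genetic variance; a per-cycle recalibration switch
  restores constant h². The degenerate target `h² = 0` (the formula's
  pole) keeps the effects but makes phenotypes pure noise with
  `σ_e² = σ_g²`, preserving a well-defined TBV scale for null checks.
- **Cycles** — 70/30 train/candidate split, BRR (one trait) or MTM
  (several), expected-loss or `Std` selection of the top `q` of the
  candidate set (`q ∈ {0.10, 0.30}`; asymmetry defaults `α, τ = 0.9` at
  10% pressure, `0.7` at 30%), doubled-haploid crossing of random distinct
  parent pairs to recover `n`. Ten cycles and 20 replicates by default;
  per-cycle records hold genetic and phenotypic means and variances, the
  standardized response `(μ_i − μ₁)/σ₁` and scaled variance `σ_i²/σ₁²`
  (cycle 1 as reference), on the TBV scale with phenotypic-scale columns
  alongside.

What the generator does *not* emulate: linkage and LD decay (loci assort
independently), mutation, dominance/epistasis, genotype-by-environment
effects, overlapping generations, or pedigree structure beyond the single
crossing scheme. Passing tests therefore demonstrate correctness of the
decision machinery under an idealized additive architecture, not
performance on real breeding data. Because founder size, locus count and
effect scales are free parameters of the design, multi-cycle outcome
magnitudes are reproduced qualitatively (positive response, declining
variance, null behavior at h² = 0), not as specific table values.

## Numerical choices

- Degenerate truncation: `z < 1e−12` raises.
- GRM: `K = WW'/c` with `c = trace(WW')/n`, so `diag(K)` averages exactly 1.
- `K` eigenvalues are floored at the 1e−8 jitter before whitening.
- Selection counts are `round(q·n)`; a zero count raises rather than
  silently selecting nobody.
- Ranking ties break by identifier; `Std` ranks descending by
  posterior-mean BV.
- Welch's t is used for replicate comparisons (unequal variances across
  selection criteria are the norm); Hotelling's T² uses the exact F
  transform `(n₁+n₂−t−1)T²/((n₁+n₂−2)t)`.

## Problem sizes used in the bundled checks

The test suite and acceptance script use desk-scale designs chosen as the
package's own defaults: founder calibration at `n = p = 1000`; sampler
recovery at `n = 300, p = 100` (BRR) and `n = 200, p = 250` over 20 seeds
(MTM); end-to-end programs at `n = 150, p = 300`, 10 cycles, 10
replicates, 300 retained draws after 300 burn-in. At these sizes the full
suite runs in a few minutes on one core.

## Known limitations

- The equal-variance assumption (`Y_o` shares `σ²`/`P` with the base
  population) is inherited from the decision framework; candidates with
  genuinely different predictive variances are only distinguished through
  the Monte-Carlo averaging over draws.
- The multivariate Energy Score is estimated from one predictive draw per
  posterior draw; its Monte-Carlo error is O(m^−1/2) in the retained chain
  length, so short chains rank near-tied candidates noisily.
- Inverse-Wishart priors shrink `G` and `R` toward halves of the sample
  covariance; with few training lines the G/R split is weakly identified
  (correlation signs are recovered reliably, magnitudes less so).
- No convergence diagnostics beyond finiteness checks; chains of the
  default length mix well for these conjugate updates, but users fitting
  unusual data should inspect the stored draws.
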