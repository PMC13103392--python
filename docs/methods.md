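# Methods

This note documents the models, numerical choices and limitations behind
`hitquant`.

## The phenotype

The mortality index for an experimental unit is
MI = 100 × (p̂_hit − p̂_sham), with p̂ the death proportion at 24 h in the
trauma and sham vials. MI is kept raw: it may be negative (sham mortality
exceeding trauma mortality), it is never clipped or variance-stabilized, and
proportions are always derived from stored integer counts, never stored
themselves. In pooled-baseline designs the sham term is the *unweighted mean
of sham-vial proportions* (each vial one observation); a
`baseline="pooled_counts"` flag switches to total deaths / total flies for
sensitivity analysis. A missing sham arm in a paired design is an error, not
an implicit zero baseline.

## Half-sib variance components

The response is dam-level MI — one value per dam — so dam effects are
confounded with the residual and are deliberately not modelled as a separate
term. The model is the unbalanced one-way random-effects model with an
optional block fixed effect:

    MI_ij = μ + block_b(ij) + u_i + e_ij,  u_i ~ N(0, σ²_s), e_ij ~ N(0, σ²_e).

*Estimation.* Restricted likelihood is profiled over γ = σ²_s/σ²_e. For each
sire family of size n_i, (I + γJ)⁻¹ = I − (γ/(1+γn_i))J and
log|I + γJ| = log(1+γn_i), so one evaluation costs O(n). β and σ²_e are
profiled out in closed form. The search evaluates a 61-point log-spaced grid
on γ ∈ [1e−8, 1e4], then Brent minimization (tolerance 1e−12 on log γ)
between the bracketing neighbours, and compares against the explicit boundary
γ = 0; the boundary estimate σ̂²_s = 0 is returned when it has the higher
restricted likelihood. On balanced designs with an interior optimum this
REML estimate coincides with the expected-mean-squares estimator, which is
also computed (`anova_varcomp`, with n0 = (N − Σn_i²/N)/(a−1) and negative
moment estimates flagged and clamped) as an independent cross-check. The
implementation agrees with lme4's REML fit to ~1e−6 on identical data (see
the test suite's oracle test).

*Testing.* The sire term is tested by χ² = 2(ℓ_full − ℓ_null) of the REML
criteria with identical fixed effects, referred to χ² with df = 1. Because
the null places σ²_s on the boundary of its parameter space, this reference
is conservative; the 50:50 mixture (0.5·χ²₀ + 0.5·χ²₁) p-value is reported
alongside as `p_boundary_mixture`. The df = 1 convention is the primary
output because it is the convention most half-sib analyses report.

*Derived quantities.* V_A = 4σ̂²_s (paternal half-sibs expose a quarter of
the additive variance between sire families; epistatic contributions are
assumed negligible). V_P = σ̂²_s + σ̂²_e **from the dam-level model**: this
phenotypic variance refers to dam means, not individual flies, so h² = V_A/V_P
can exceed 1 and should be read as 4× the intraclass correlation. CV_A =
100·√V_A / x̄ uses the unweighted grand mean of dam-level MI by default; a
family-size-weighted mean is available (`cva_weighted`). Block enters as a
fixed effect by default and can be dropped (`include_block=False`); the
block/weighting conventions are exposed as flags because different labs make
different choices here.

Degenerate inputs: a single sire, a rank-deficient fixed-effect design, or
zero residual variation all raise `DegenerateDataError` rather than
returning numbers.

## Resampling machinery

*t-tests and Levene.* Student (pooled, df = n₁+n₂−2), Welch
(Satterthwaite df) and one-sample t-tests delegate to scipy; effect signs
follow input order (group_a − group_b). Levene's test defaults to the median
centre (Brown–Forsythe), mean available.

*CV randomization.* Statistic T = |CV(x) − CV(y)| with CV = 100·SD/mean
(a CV-ratio statistic is available). All values are pooled and reallocated
at random to the original group sizes; p = (1 + #{T* ≥ T_obs})/(R + 1)
(add-one rule, so p ≥ 1/(R+1) and p = 1 for duplicated samples). The pooled
sample is sorted and the smaller group filled first, which makes the
permutation stream — and therefore p — exactly invariant to swapping the two
input samples. Permuted replicates with a zero group mean have no CV; they
are counted as exceeding (conservative) and tallied in `n_degenerate`.

*Bootstrap correlation.* Point estimate is Pearson r on complete pairs
(rows missing either trait are dropped pairwise). Pairs are resampled with
replacement; the 95% CI is the 2.5/97.5 percentile of the bootstrap
distribution, and the two-sided p is the sign-crossing rule
2·min(frac(r* ≤ 0), frac(r* ≥ 0)) clamped to 1. Percentile rather than BCa
was chosen for transparency; long-run CI coverage measured on bivariate
normal data is ≈93.6% at n = 49 and ≈94.0% at n = 169 (slight undercoverage
typical of the percentile method at these sample sizes), while the test's
type-I error at ρ = 0 is well calibrated. Zero-variance resamples are
redrawn and counted.

*KS vs Poisson.* D = sup over the integer support of |empirical CDF −
Poisson(λ̂) CDF| with λ̂ the sample mean. The reported p uses the asymptotic
Kolmogorov distribution — the conventional test, conservative because λ is
estimated (the Lilliefors issue) — and a parametric-bootstrap p
(re-simulating and re-estimating λ) is reported as the honest diagnostic.

## Power simulation

Group a is drawn from the baseline — Normal(μ, σ²), or resampling an
observed MI sample with replacement when one is supplied — and group b from
the same baseline with its mean shifted by `effect_fraction × baseline mean`
(multiplicative effect on the mean only, variance unchanged; an
additive-percentage-points mode exists because "an X% increase" is ambiguous).
The chosen two-sided t-test (Student by default) is applied per replicate;
power is the rejection fraction with MC-SE √(p(1−p)/R). Against the
closed-form noncentral-t power the simulator agrees within Monte-Carlo error
at all tested effect sizes.

## Synthetic data generator

The generator emulates the variance structure of family-structured binomial
mortality data — not genomes, linkage or selection.

*Half-sib design.* Sire effects s_i ~ N(0, σ_s²) and dam effects
d_ij ~ N(0, σ_d²) act on the logit of hit-vial mortality:
p_hit = expit(logit(p_sham) + μ_hit + s_i + d_ij + block). Sham mortality is
a shared constant because MI subtracts the sham baseline and the assay
treats it as a nuisance; sham deaths are Binomial(n, p_sham). Offspring
counts are Poisson(λ) per dam, split evenly into the two arms with the odd
fly going to the hit vial (deterministic, documented). Dams with no
offspring are dropped, emulating dams that fail to reproduce.

*Default conditions.* 55 sires × 3 dams with 19% dam dropout (≈133
productive dams), λ = 79 offspring per dam, two blocks (block shift 0.2 on
the logit scale), p_sham = 0.02 (the assay's sham mortality is a small
nuisance whose magnitude is not critical; 2% is a realistic housekeeping
loss), μ_hit = 2.63 (mean trauma mortality ≈ 22%, mean MI ≈ 23%), σ_s =
0.305 and σ_d = 0.53. The two SDs were calibrated once, via the package's
own Monte-Carlo mapping to the MI scale, so that the implied study
conditions are ICC = 0.171 (h² = 4·ICC = 0.685) and CV_A = 46.2% — the
regime the package is designed to analyse. Two-group defaults emulate an
inbreeding-style contrast: 34 units per group, ~22 flies per vial,
hit-arm mortality 8.7% over a 2% sham baseline (mean MI ≈ 6.7), between-unit
logit SD 0.8.

*Truth bookkeeping.* Every dataset carries a `SimTruth` with its config and
realized random effects. Because the logit→MI map is nonlinear, the implied
MI-scale components have no closed form; they are computed lazily by a
large Monte-Carlo (100,000 sires × 40 dams), block-centred, with the MC
noise in the sire-mean variance subtracted and the binomial sampling
variance evaluated at Poisson family sizes. These values are flagged
`approximate` and are seed-independent (configs differing only in seed share
one truth).

*What the generator does not emulate.* Real vials share environments beyond
the block term (humidity, handling order); sham mortality may covary with
family; hit and sham arms of one dam share rearing effects that here enter
only through the dam term; MI values are equi-correlated within sires with
Gaussian effects, whereas real sire effects need not be Gaussian. Passing
recovery tests therefore demonstrates correctness of the estimators under
the assumed variance structure, not robustness to these violations.

*Randomness.* All generators use counter-based Philox streams keyed on
(seed, stream-id), so identical seeds give bit-identical datasets regardless
of the order in which generators are invoked.

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` use the study-scale designs
directly (55 sires / ~133 dams; 34, 25 and ~41 units per group; 49- and
169-line trait tables) and replicate counts of 200–400 datasets for
calibration and recovery experiments, 2,000–20,000 resamples for bootstrap
and randomization procedures. These sizes keep every check's Monte-Carlo
error well below the asserted tolerances while completing in seconds to a
couple of minutes.

## Known limitations

- The dam-level response means σ²_e mixes dam genetic/maternal effects with
  binomial sampling noise; the package cannot separate them, and h² inherits
  the dam-mean definition of V_P (see above).
- The LRT's df = 1 convention is conservative at the boundary; use the
  reported mixture p when calibrated error rates matter.
- Percentile bootstrap CIs for correlations undercover slightly at n ≲ 50.
- The KS asymptotic p with an estimated rate is conservative; prefer the
  bootstrap p for inference.
- The CV randomization test assumes exchangeability of values under the
  null; it tests equality of distributions through the CV lens, not CV
  equality under arbitrary distributional differences.
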