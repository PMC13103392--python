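# hitquant

Quantitative genetics of trauma-induced mortality in *Drosophila
melanogaster*. The package implements the statistical machinery used to study
how genetic and environmental variation shape the risk of death after blunt
trauma (the "high-impact trauma", HIT, assay): the mortality index, additive
genetic variance estimation from a half-sib breeding design, two-group
contrasts with resampling tests, bootstrap trait correlations, Monte-Carlo
power analysis, and a synthetic-data generator that emulates the
family-structured binomial mortality data such experiments produce.

It is written for quantitative and evolutionary geneticists who want to
analyse vial-level mortality counts from controlled breeding or condition
manipulation experiments, or to plan such experiments by simulation.

## The statistics

**Mortality index.** Each experimental unit contributes a trauma (hit) vial
and a sham vial. The phenotype is

    MI = 100 × (p̂_hit − p̂_sham),

the difference in death proportions, in percentage points. In mass-reared
designs without per-unit sham vials, the baseline is the average death
proportion across all sham vials of the group (pooled mode).

**Additive genetic variance.** With sires mated to several dams each and one
MI value per dam, the one-way random-effects model

    MI_ij = μ + block_b + u_i + e_ij,  u_i ~ N(0, σ²_s),  e_ij ~ N(0, σ²_e)

is fit by REML (profile likelihood over γ = σ²_s/σ²_e with the closed-form
compound-symmetry inverse per sire family). In a paternal half-sib design
V_A = 4σ²_s; the package reports V_P = σ²_s + σ²_e, h² = V_A/V_P, and the
coefficient of additive genetic variation CV_A = 100·√V_A / x̄. The sire term
is tested by a REML likelihood-ratio test on χ²₁ (the 50:50 boundary-mixture
p is reported as a diagnostic), and an expected-mean-squares (ANOVA)
estimator is computed alongside as an independent cross-check.

**Resampling tests.** Student/Welch/one-sample t-tests and Levene's test
(scipy-backed); a randomization test for differences in coefficients of
variation (group labels permuted, add-one p-value); pair-resampling bootstrap
for Pearson correlations (percentile CI, sign-crossing p); and a
Kolmogorov–Smirnov goodness-of-fit check of offspring counts against a
Poisson distribution.

**Power.** Monte-Carlo power of a two-sample t-test to detect a relative
increase in mean MI, with Normal draws or resampling of an observed MI
sample, validated against the closed-form noncentral-t power.

## Worked example

Simulate a half-sib breeding experiment at the default study scale (55 sires,
3 dams each with ~19% dropout, ~79 offspring per dam split into hit and sham
vials, two blocks) and estimate its variance components:

```python
from hitquant import (HalfSibSimConfig, generate_half_sib, run_halfsib)

vials, truth = generate_half_sib(HalfSibSimConfig(seed=11))
report = run_halfsib(vials)
vc = report.results["varcomp"]
print(f"sires={vc.n_sires} dams={vc.n_dams}")
print(f"sigma2_sire={vc.sigma2_sire:.1f}  sigma2_resid={vc.sigma2_resid:.1f}")
print(f"LRT chi2={vc.chi2:.2f} (df={vc.df}, p={vc.p:.4f})")
print(f"h2={vc.h2:.3f}  CVA={vc.cva:.1f}%  mean MI={vc.grand_mean:.1f}%")
print("implied truth:", {k: round(v, 3) for k, v in truth.mi_scale.items()
                         if isinstance(v, float)})
```

prints

```
sires=55 dams=125
sigma2_sire=40.2  sigma2_resid=130.1
LRT chi2=3.41 (df=1, p=0.0649)
h2=0.945  CVA=55.0%  mean MI=23.1%
implied truth: {'mean_mi': 23.476, 'sigma2_sire': 29.443, 'sigma2_resid': 142.577,
 'icc': 0.171, 'va': 117.772, 'vp': 172.02, 'h2': 0.685, 'cva': 46.227}
```

One simulated experiment of 125 dams estimates the sire variance with
substantial sampling scatter against the generating truth (σ²_s = 29.4,
h² = 0.685) — exactly the uncertainty a real experiment of
this size carries (here σ̂²_s = 40.2, h² = 0.94); averaging over replicate
simulations recovers the truth (see the test suite's parameter-recovery
checks).

The same analyses are available from the shell:

```sh
hitquant simulate --config halfsib.yaml --seed 3 --out sim/
hitquant mi --vials sim/vials.csv --out sim/mi.csv
hitquant varcomp --mi-records sim/mi.csv
hitquant compare --vials twogroup.csv --seed 1
hitquant corr --traits lines.csv --pair mi,viability --seed 2
hitquant power --n 34 --effect 0.6 --baseline-mean 6.7 --baseline-sd 8.955
```

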