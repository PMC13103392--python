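"""Two-group tests, CV randomization, bootstrap correlation, KS-vs-Poisson.

Conventions
-----------
* Effect sign is ``group_a - group_b`` in input order for all two-sample
  tests (so a higher second group gives a negative t).
* All resampling procedures take an explicit ``seed`` and replicate count and
  are bit-reproducible; randomization p-values use the add-one rule
  p = (1 + #{T* >= T_obs}) / (n_reps + 1) so p is never 0.
* CV = 100 * SD / mean (percent), sample SD with ddof=1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats


class InsufficientDataError(ValueError):
    """Too few observations for the requested procedure."""


class DegenerateSampleError(ValueError):
    """The sample has no usable variation (or a zero mean where a CV is needed)."""


@dataclass
class TestResult:
    statistic: float
    df: float
    p: float
    effect: float
    effect_ci_low: float
    effect_ci_high: float
    method: str


@dataclass
class KSPoissonResult(TestResult):
    """KS goodness of fit to Poisson(lambda_hat); lambda estimated from the data.

    ``p`` is the conventional asymptotic Kolmogorov p-value (anticonservative
    assumptions about estimated parameters make it conservative in practice,
    the Lilliefors issue); ``p_bootstrap`` is the honest parametric-bootstrap
    diagnostic.
    """
    lambda_hat: float = float("nan")
    p_bootstrap: float = float("nan")
    n: int = 0


@dataclass
class GroupComparison:
    """Two-group summary: location test plus CV randomization test."""

    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    cv_a: float
    cv_b: float
    t_result: TestResult
    cv_stat_obs: float
    cv_randomization_p: float
    n_degenerate: int            # permuted replicates with an undefined CV
    n_reps: int
    seed: int | None


@dataclass
class CorrelationEstimate:
    r: float
    n: int
    boot_ci_low: float
    boot_ci_high: float
    boot_p: float
    n_reps: int
    n_degenerate: int            # zero-variance resamples that were redrawn
    seed: int | None


# ---------------------------------------------------------------------------
# t-tests and Levene (scipy-backed)
# ---------------------------------------------------------------------------

def _check_two_samples(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    return x, y


def _two_sample_t(x, y, equal_var: bool, label: str) -> TestResult:
    x, y = _check_two_samples(x, y)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
        raise DegenerateSampleError("t undefined: both samples constant and equal")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    return TestResult(statistic=float(res.statistic), df=float(res.df),
                      p=float(res.pvalue), effect=float(np.mean(x) - np.mean(y)),
                      effect_ci_low=float(ci.low), effect_ci_high=float(ci.high),
                      method=label)


def student_t_test(x, y) -> TestResult:
    """Pooled-variance two-sample t-test, df = n1 + n2 - 2."""
    return _two_sample_t(x, y, equal_var=True, label="student_t")


def welch_t_test(x, y) -> TestResult:
    """Welch two-sample t-test with Satterthwaite fractional df."""
    return _two_sample_t(x, y, equal_var=False, label="welch_t")


def one_sample_t(x, mu0: float = 0.0) -> TestResult:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("one-sample t needs n >= 2")
    if np.var(x, ddof=1) == 0:
        raise DegenerateSampleError("t undefined: sample is constant")
    res = stats.ttest_1samp(x, mu0)
    ci = res.confidence_interval(0.95)
    return TestResult(statistic=float(res.statistic), df=float(len(x) - 1),
                      p=float(res.pvalue), effect=float(np.mean(x) - mu0),
                      effect_ci_low=float(ci.low - mu0),
                      effect_ci_high=float(ci.high - mu0),
                      method="one_sample_t")


def levene_test(x, y, center: str = "median") -> TestResult:
    """Levene/Brown-Forsythe test of equal variances (F on |value - center|)."""
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    x, y = _check_two_samples(x, y)
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise DegenerateSampleError("Levene F undefined: both groups constant")
    res = stats.levene(x, y, center=center)
    sd_x, sd_y = np.std(x, ddof=1), np.std(y, ddof=1)
    return TestResult(statistic=float(res.statistic),
                      df=float(len(x) + len(y) - 2),
                      p=float(res.pvalue), effect=float(sd_x - sd_y),
                      effect_ci_low=float("nan"), effect_ci_high=float("nan"),
                      method=f"levene[{center}]")


# ---------------------------------------------------------------------------
# CV randomization test
# ---------------------------------------------------------------------------

def coefficient_of_variation(x) -> float:
    """CV in percent: 100 * sample SD / mean.  Undefined when mean == 0."""
    x = np.asarray(x, dtype=float)
    m = np.mean(x)
    if m == 0:
        raise DegenerateSampleError("CV undefined: sample mean is zero")
    return 100.0 * np.std(x, ddof=1) / m


def _row_cv(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row CV for a 2-d array; returns (cv, defined_mask)."""
    n = values.shape[1]
    m = values.mean(axis=1)
    var = (np.sum(values ** 2, axis=1) - n * m ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    ok = m != 0
    cv = np.full(values.shape[0], np.nan)
    cv[ok] = 100.0 * np.sqrt(var[ok]) / m[ok]
    return cv, ok


def cv_randomization_test(x, y, n_reps: int = 10_000, seed: int | None = None,
                          statistic: str = "abs_diff") -> GroupComparison:
    """Randomization test for a difference in coefficients of variation.

    Observed statistic T = |CV(x) - CV(y)| (``statistic="abs_diff"``, default)
    or T = max(CV ratio, 1/ratio) (``statistic="ratio"``).  All values are
    pooled and repeatedly reallocated at random to the original group sizes;
    permuted replicates whose group mean is zero have no CV and are counted
    as exceeding the observed statistic (conservative) and tallied in
    ``n_degenerate``.  Also reports the Student t-test on the group means.
    """
    x, y = _check_two_samples(x, y)
    if statistic not in ("abs_diff", "ratio"):
        raise ValueError("statistic must be 'abs_diff' or 'ratio'")
    cv_x = coefficient_of_variation(x)
    cv_y = coefficient_of_variation(y)

    def stat(a_cv, b_cv):
        if statistic == "abs_diff":
            return abs(a_cv - b_cv)
        r = a_cv / b_cv
        return max(abs(r), abs(1.0 / r))

    t_obs = stat(cv_x, cv_y)
    # canonicalize so the result is invariant to swapping x and y: permute the
    # sorted pool and fill the smaller group first
    n_a, n_b = sorted((len(x), len(y)))
    pooled = np.sort(np.concatenate([x, y]))
    n = len(pooled)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    # random reallocations via row-wise argsort of uniforms
    perm = np.argsort(rng.random((n_reps, n)), axis=1)
    shuffled = pooled[perm]
    cv_a, ok_a = _row_cv(shuffled[:, :n_a])
    cv_b, ok_b = _row_cv(shuffled[:, n_a:])
    ok = ok_a & ok_b
    if statistic == "abs_diff":
        t_star = np.abs(cv_a - cv_b)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = cv_a / cv_b
            t_star = np.maximum(np.abs(ratio), np.abs(1.0 / ratio))
    n_degenerate = int(np.sum(~ok))
    exceed = int(np.sum(t_star[ok] >= t_obs)) + n_degenerate
    p = (1 + exceed) / (n_reps + 1)

    t_res = student_t_test(x, y)
    return GroupComparison(
        n_a=len(x), n_b=len(y),
        mean_a=float(np.mean(x)), mean_b=float(np.mean(y)),
        sd_a=float(np.std(x, ddof=1)), sd_b=float(np.std(y, ddof=1)),
        cv_a=float(cv_x), cv_b=float(cv_y), t_result=t_res,
        cv_stat_obs=float(t_obs), cv_randomization_p=float(p),
        n_degenerate=n_degenerate, n_reps=n_reps, seed=seed)


# ---------------------------------------------------------------------------
# bootstrap Pearson correlation
# ---------------------------------------------------------------------------

def _row_pearson(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = xs.shape[1]
    mx = xs.mean(axis=1)
    my = ys.mean(axis=1)
    cov = (xs * ys).sum(axis=1) / n - mx * my
    vx = (xs ** 2).sum(axis=1) / n - mx ** 2
    vy = (ys ** 2).sum(axis=1) / n - my ** 2
    ok = (vx > 0) & (vy > 0)
    r = np.full(xs.shape[0], np.nan)
    r[ok] = cov[ok] / np.sqrt(vx[ok] * vy[ok])
    return np.clip(r, -1.0, 1.0), ok


def bootstrap_correlation(x, y, n_reps: int = 10_000, seed: int | None = None,
                          ci: str = "percentile") -> CorrelationEstimate:
    """Pearson correlation with pair-resampling bootstrap CI and p-value.

    The point estimate is Pearson r on complete pairs.  Pairs are resampled
    with replacement ``n_reps`` times; the 95% CI is the 2.5/97.5 percentile
    of the bootstrap r distribution and the two-sided p-value is the
    sign-crossing rule 2 * min(frac(r* <= 0), frac(r* >= 0)), clamped to 1.
    Zero-variance resamples are redrawn and counted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must be paired (equal length)")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        raise InsufficientDataError("bootstrap correlation needs n >= 3 complete pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateSampleError("correlation undefined: a variable is constant")
    if ci != "percentile":
        raise ValueError("only the percentile CI is implemented")

    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    idx = rng.integers(0, n, size=(n_reps, n))
    r_boot, good = _row_pearson(x[idx], y[idx])
    n_degenerate = 0
    for _ in range(100):                    # redraw degenerate resamples
        bad = ~good
        if not bad.any():
            break
        n_degenerate += int(bad.sum())
        idx_new = rng.integers(0, n, size=(int(bad.sum()), n))
        r_new, good_new = _row_pearson(x[idx_new], y[idx_new])
        r_boot[bad] = r_new
        good[bad] = good_new
    r_boot = r_boot[np.isfinite(r_boot)]
    lo, hi = np.percentile(r_boot, [2.5, 97.5])
    frac_le = np.mean(r_boot <= 0)
    frac_ge = np.mean(r_boot >= 0)
    p = min(1.0, 2.0 * min(frac_le, frac_ge))
    return CorrelationEstimate(r=r_obs, n=n,
                               boot_ci_low=float(np.clip(lo, -1, 1)),
                               boot_ci_high=float(np.clip(hi, -1, 1)),
                               boot_p=float(p), n_reps=n_reps,
                               n_degenerate=n_degenerate, seed=seed)


# ---------------------------------------------------------------------------
# KS goodness of fit to a Poisson distribution
# ---------------------------------------------------------------------------

def _ks_poisson_d(counts: np.ndarray, lam: float) -> float:
    """sup_k |F_emp(k) - F_Poisson(k)| over the integer support."""
    n = len(counts)
    kmax = int(counts.max())
    ks = np.arange(kmax + 1)
    sorted_counts = np.sort(counts)
    f_emp = np.searchsorted(sorted_counts, ks, side="right") / n
    f_pois = stats.poisson.cdf(ks, lam)
    return float(np.max(np.abs(f_emp - f_pois)))


def ks_poisson_test(counts, n_boot: int = 2000,
                    seed: int | None = None) -> KSPoissonResult:
    """KS test of integer counts against Poisson(lambda = sample mean).

    D is the supremum over the integer support of |empirical CDF - Poisson
    CDF|.  The reported ``p`` uses the asymptotic Kolmogorov distribution
    (conventional, conservative when lambda is estimated); ``p_bootstrap``
    re-simulates Poisson samples, re-estimating lambda each time.
    """
    arr = np.asarray(counts)
    if arr.size < 5:
        raise InsufficientDataError("KS test needs n >= 5 counts")
    as_float = arr.astype(float)
    if np.any(as_float < 0) or np.any(as_float != np.round(as_float)):
        raise ValueError("counts must be non-negative integers")
    c = as_float.astype(int)
    n = len(c)
    lam = float(np.mean(c))
    if lam == 0:
        raise DegenerateSampleError("all counts are zero; Poisson rate is 0")
    d_obs = _ks_poisson_d(c, lam)
    p_asym = float(special.kolmogorov(math.sqrt(n) * d_obs))
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    sims = rng.poisson(lam, size=(n_boot, n))
    exceed = 0
    for row in sims:
        lam_b = float(row.mean())
        if lam_b == 0:
            continue
        if _ks_poisson_d(row, lam_b) >= d_obs:
            exceed += 1
    p_boot = (1 + exceed) / (n_boot + 1)
    se = math.sqrt(lam / n)
    return KSPoissonResult(statistic=d_obs, df=float("nan"), p=p_asym,
                           effect=lam, effect_ci_low=lam - 1.96 * se,
                           effect_ci_high=lam + 1.96 * se,
                           method="ks_poisson", lambda_hat=lam,
                           p_bootstrap=float(p_boot), n=n)
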