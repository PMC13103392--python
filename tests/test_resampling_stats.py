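"""t-tests, Levene, CV randomization, bootstrap correlation, KS-vs-Poisson."""

import itertools

import numpy as np
import pytest
from scipy import stats

from hitquant import (DegenerateSampleError, InsufficientDataError,
                      bootstrap_correlation, coefficient_of_variation,
                      cv_randomization_test, ks_poisson_test, levene_test,
                      one_sample_t, student_t_test, welch_t_test)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def test_identical_samples_give_t_zero_p_one(rng):
    x = rng.normal(0, 1, 10)
    res = student_t_test(x, x.copy())
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_hand_computed_pooled_t():
    # mean diff -3, pooled var 1, SE = sqrt(1/3 + 1/3)
    res = student_t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
    assert res.statistic == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
    assert res.statistic == pytest.approx(-3.674, abs=5e-4)
    assert res.df == 4
    assert res.effect == pytest.approx(-3.0)
    assert res.effect_ci_low < res.effect < res.effect_ci_high


@pytest.mark.parametrize("n1,n2,expected_df", [(34, 34, 66), (25, 25, 48), (38, 44, 80)])
def test_student_df_convention_matches_designs(rng, n1, n2, expected_df):
    """df = n1 + n2 - 2 for the three experimental sample sizes."""
    res = student_t_test(rng.normal(0, 1, n1), rng.normal(0, 1, n2))
    assert res.df == expected_df


def test_welch_equals_student_for_equal_sizes_and_variances():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = x + 0.5
    s = student_t_test(x, y)
    w = welch_t_test(x, y)
    assert w.statistic == pytest.approx(s.statistic, rel=1e-12)
    assert w.df == pytest.approx(s.df)


def test_one_sample_t_and_sign_convention(rng):
    x = rng.normal(5, 1, 40)
    res = one_sample_t(x, 0.0)
    assert res.statistic > 0 and res.df == 39
    assert res.effect == pytest.approx(np.mean(x))
    # group_a - group_b: higher second group => negative t
    neg = student_t_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert neg.statistic < 0


# ---------------------------------------------------------------------------
# Levene
# ---------------------------------------------------------------------------

def test_levene_detects_tenfold_spread_difference(rng):
    x = rng.normal(0, 1, 51)
    y = rng.normal(0, 10, 51)
    assert levene_test(x, y).p < 0.01


def test_levene_null_p_roughly_uniform(rng):
    ps = [levene_test(rng.normal(0, 2, 30), rng.normal(0, 2, 30)).p
          for _ in range(300)]
    # calibrated: rejection rate at 0.05 within binomial 99% CI
    rate = np.mean(np.array(ps) < 0.05)
    assert 0.05 - 2.58 * np.sqrt(0.05 * 0.95 / 300) <= rate \
        <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / 300)


def test_levene_centers_differ_on_skewed_sample(rng):
    x = rng.exponential(1, 60)
    y = rng.exponential(2, 60)
    med = levene_test(x, y, center="median")
    mean = levene_test(x, y, center="mean")
    assert med.method != mean.method
    assert med.statistic != pytest.approx(mean.statistic)


# ---------------------------------------------------------------------------
# CV randomization
# ---------------------------------------------------------------------------

def test_cv_duplicated_sample_gives_p_one(rng):
    x = rng.normal(10, 3, 20)
    res = cv_randomization_test(x, x.copy(), n_reps=500, seed=1)
    assert res.cv_stat_obs == pytest.approx(0.0, abs=1e-12)
    assert res.cv_randomization_p == 1.0


def test_cv_randomization_matches_exhaustive_enumeration():
    x = np.array([8.0, 10.0, 12.0])
    y = np.array([5.0, 10.0, 15.0])

    def cv(v):
        return 100 * np.std(v, ddof=1) / np.mean(v)

    t_obs = abs(cv(x) - cv(y))
    pooled = np.concatenate([x, y])
    exceed = total = 0
    for idx in itertools.combinations(range(6), 3):     # all 20 label splits
        a = pooled[list(idx)]
        b = pooled[[i for i in range(6) if i not in idx]]
        total += 1
        exceed += abs(cv(a) - cv(b)) >= t_obs - 1e-12
    p_exact = exceed / total
    n_reps = 20_000
    res = cv_randomization_test(x, y, n_reps=n_reps, seed=7)
    assert res.cv_randomization_p == pytest.approx(p_exact, abs=2 / np.sqrt(n_reps))


def test_cv_randomization_symmetric_and_reproducible(rng):
    x = rng.normal(10, 2, 12)
    y = rng.normal(10, 4, 12)
    a = cv_randomization_test(x, y, n_reps=999, seed=3)
    b = cv_randomization_test(y, x, n_reps=999, seed=3)
    assert a.cv_randomization_p == b.cv_randomization_p
    again = cv_randomization_test(x, y, n_reps=999, seed=3)
    assert again.cv_randomization_p == a.cv_randomization_p
    assert a.cv_randomization_p >= 1 / 1000          # add-one rule floor


def test_cv_requires_nonzero_mean():
    with pytest.raises(DegenerateSampleError):
        coefficient_of_variation([-1.0, 1.0])


def test_cv_ratio_statistic_flag(rng):
    x = rng.normal(10, 2, 15)
    y = rng.normal(10, 5, 15)
    res = cv_randomization_test(x, y, n_reps=999, seed=5, statistic="ratio")
    assert res.cv_stat_obs >= 1.0


# ---------------------------------------------------------------------------
# bootstrap correlation
# ---------------------------------------------------------------------------

def test_collinear_pair_gives_r_one_ci_degenerate(rng):
    x = rng.normal(0, 1, 30)
    y = 2 * x + 1
    est = bootstrap_correlation(x, y, n_reps=500, seed=1)
    assert est.r == pytest.approx(1.0)
    assert est.boot_ci_low == pytest.approx(1.0) and est.boot_ci_high == pytest.approx(1.0)
    assert est.boot_p == pytest.approx(0.0)


def test_bootstrap_ci_within_bounds_and_brackets_estimate(rng):
    for _ in range(20):
        x = rng.normal(0, 1, 25)
        y = 0.5 * x + rng.normal(0, 1, 25)
        est = bootstrap_correlation(x, y, n_reps=800, seed=11)
        assert -1.0 <= est.boot_ci_low <= est.boot_ci_high <= 1.0
        assert est.boot_ci_low <= est.r <= est.boot_ci_high


def test_bootstrap_handles_missing_pairs():
    x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
    y = np.array([2.0, 4.1, 6.0, np.nan, 10.2, 11.9])
    est = bootstrap_correlation(x, y, n_reps=500, seed=2)
    assert est.n == 4


def test_bootstrap_errors():
    with pytest.raises(InsufficientDataError):
        bootstrap_correlation([1.0, 2.0], [2.0, 3.0])
    with pytest.raises(DegenerateSampleError):
        bootstrap_correlation([1.0, 1.0, 1.0], [2.0, 3.0, 4.0])


def test_bootstrap_reproducible_under_seed(rng):
    x = rng.normal(0, 1, 40)
    y = rng.normal(0, 1, 40)
    a = bootstrap_correlation(x, y, n_reps=1000, seed=9)
    b = bootstrap_correlation(x, y, n_reps=1000, seed=9)
    assert (a.boot_ci_low, a.boot_ci_high, a.boot_p) == \
        (b.boot_ci_low, b.boot_ci_high, b.boot_p)


# ---------------------------------------------------------------------------
# KS vs Poisson
# ---------------------------------------------------------------------------

def test_ks_statistic_matches_brute_force_enumeration():
    """All counts equal to an integer lambda: D computable by direct CDF walk."""
    counts = np.full(20, 5)
    res = ks_poisson_test(counts, n_boot=200, seed=1)
    # brute force: empirical CDF is 0 below 5, 1 from 5 on
    lam = 5.0
    d_expected = max(
        max(stats.poisson.cdf(k, lam) for k in range(5)),          # F_emp = 0
        max(abs(1 - stats.poisson.cdf(k, lam)) for k in range(5, 60)))
    assert res.statistic == pytest.approx(d_expected, abs=1e-12)
    assert res.lambda_hat == 5.0


def test_ks_null_calibration_at_study_scale(rng):
    """Poisson data at n = 133: asymptotic p conservative, rarely small."""
    ps = []
    for _ in range(300):
        counts = rng.poisson(79, 133)
        ps.append(ks_poisson_test(counts, n_boot=1, seed=0).p)
    ps = np.array(ps)
    assert np.mean(ps < 0.05) <= 0.05          # conservative with estimated lambda
    assert np.mean(ps) > 0.5


def test_ks_bootstrap_p_detects_overdispersion(rng):
    counts = rng.negative_binomial(5, 0.06, 150)       # strongly overdispersed
    res = ks_poisson_test(counts, n_boot=500, seed=3)
    assert res.p_bootstrap < 0.01


def test_ks_input_validation():
    with pytest.raises(InsufficientDataError):
        ks_poisson_test([1, 2, 3])
    with pytest.raises(ValueError, match="non-negative integers"):
        ks_poisson_test([1.5, 2, 3, 4, 5])
    with pytest.raises(ValueError, match="non-negative integers"):
        ks_poisson_test([-1, 2, 3, 4, 5])
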