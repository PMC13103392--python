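"""Generator reproducibility, record validity, and Monte-Carlo expectations."""

import dataclasses

import numpy as np
import pytest

from hitquant import (HalfSibSimConfig, LineTraitSimConfig, SimTruth,
                      TwoGroupSimConfig, bootstrap_correlation,
                      fit_sire_model_records, generate_half_sib,
                      generate_line_traits, generate_two_group,
                      paired_mi_records, student_t_test)
from hitquant.synthetic_data import ConfigError


def test_same_seed_bit_identical_different_seed_distinct():
    cfg = HalfSibSimConfig(seed=42)
    v1, _ = generate_half_sib(cfg)
    v2, _ = generate_half_sib(HalfSibSimConfig(seed=42))
    v3, _ = generate_half_sib(HalfSibSimConfig(seed=43))
    assert v1 == v2
    assert v1 != v3


def test_half_sib_records_valid_and_paired():
    vials, truth = generate_half_sib(HalfSibSimConfig(seed=5))
    for v in vials:
        assert 0 <= v.n_dead <= v.n_flies       # core invariants hold
        assert v.treatment in ("hit", "sham")
    recs, warnings = paired_mi_records(vials)
    assert not warnings                          # generator emits complete pairs
    assert all(r.baseline_mode == "paired" for r in recs)
    assert set(truth.realized["sire_effects"]) >= {r.group_id for r in recs}


def test_half_sib_paper_scale_offspring_total():
    """Default config emulates the breeding design: ~55 sires, ~133 dams,
    total offspring on the 10,496 scale (within sampling noise)."""
    totals, dams = [], []
    for k in range(10):
        vials, _ = generate_half_sib(HalfSibSimConfig(seed=600 + k))
        totals.append(sum(v.n_flies for v in vials))
        dams.append(len({v.unit_id for v in vials}))
    # expectation: 55 sires * 3 dams * (1 - 0.19) dropout * 79 offspring
    expect = 55 * 3 * 0.81 * 79
    assert abs(np.mean(totals) - expect) < 3 * np.std(totals) / np.sqrt(len(totals)) + 200
    assert 110 <= np.mean(dams) <= 155           # ~133 dams
    assert 9000 < np.mean(totals) < 12000        # 10,496-scale


def test_half_sib_null_mean_mi_near_zero():
    """sigma_s = sigma_d = 0, mu_hit = 0: MI differs from 0 only by noise."""
    cfg = HalfSibSimConfig(n_sires=200, sigma_sire=0.0, sigma_dam=0.0,
                           mu_hit=0.0, block_shift=0.0, seed=8)
    vials, _ = generate_half_sib(cfg)
    recs, _ = paired_mi_records(vials)
    mi = np.array([r.mi for r in recs])
    mc_se = mi.std(ddof=1) / np.sqrt(len(mi))
    assert abs(mi.mean()) < 3 * mc_se


def test_half_sib_null_lrt_type_one_error():
    """sigma_s = 0: LRT rejects at <= nominal rate (boundary-conservative)."""
    cfg = HalfSibSimConfig(sigma_sire=0.0)
    rej = 0
    n = 200
    for k in range(n):
        vials, _ = generate_half_sib(dataclasses.replace(cfg, seed=7000 + k))
        recs, _ = paired_mi_records(vials)
        rej += fit_sire_model_records(recs).p < 0.05
    rate = rej / n
    assert rate <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n)


def test_half_sib_truth_matches_study_conditions():
    truth = SimTruth(config=HalfSibSimConfig()).mi_scale
    assert truth["approximate"]
    assert truth["icc"] == pytest.approx(truth["h2"] / 4, rel=1e-9)
    assert 0.15 < truth["icc"] < 0.20
    assert truth["mean_mi"] > 0


def test_zero_sires_rejected():
    with pytest.raises(ConfigError):
        HalfSibSimConfig(n_sires=0)


def test_two_group_null_t_calibrated():
    cfg = TwoGroupSimConfig()
    rej = 0
    n = 300
    for k in range(n):
        vials, _, _ = generate_two_group(dataclasses.replace(cfg, seed=k))
        recs, _ = paired_mi_records(vials)
        a = [r.mi for r in recs if r.group_id == "group_a"]
        b = [r.mi for r in recs if r.group_id == "group_b"]
        rej += student_t_test(a, b).p < 0.05
    assert abs(rej / n - 0.05) <= 1.96 * np.sqrt(0.05 * 0.95 / n) + 0.01


def test_two_group_mi_difference_matches_injected_shift():
    """p_hit difference of 0.10 with no unit noise recovers a 10-point MI gap."""
    cfg = TwoGroupSimConfig(n_units_per_group=25, flies_per_vial=50,
                            p_hit_a=0.10, p_hit_b=0.20, unit_sd=0.0)
    diffs = []
    for k in range(200):
        vials, _, _ = generate_two_group(dataclasses.replace(cfg, seed=k))
        recs, _ = paired_mi_records(vials)
        a = np.mean([r.mi for r in recs if r.group_id == "group_a"])
        b = np.mean([r.mi for r in recs if r.group_id == "group_b"])
        diffs.append(b - a)
    d = np.array(diffs)
    mc_se = d.std(ddof=1) / np.sqrt(len(d))
    assert abs(d.mean() - 10.0) < 3 * mc_se


def test_two_group_mass_reduction_recovered():
    """Mass means 0.30 vs 0.24 mg: the 20% reduction is recovered within MC error."""
    cfg = TwoGroupSimConfig(mass_mean_a=0.30, mass_mean_b=0.24,
                            mass_sd_a=0.03, mass_sd_b=0.03)
    reductions = []
    for k in range(100):
        _, masses, _ = generate_two_group(dataclasses.replace(cfg, seed=k))
        a = np.mean([m.dry_mass for m in masses if m.group_id == "group_a"])
        b = np.mean([m.dry_mass for m in masses if m.group_id == "group_b"])
        reductions.append(1 - b / a)
    r = np.array(reductions)
    assert abs(r.mean() - 0.20) < 3 * r.std(ddof=1) / np.sqrt(len(r))


def test_two_group_pooled_layout_and_unit_minimum():
    vials, _, _ = generate_two_group(TwoGroupSimConfig(layout="pooled", seed=1))
    shams = [v for v in vials if v.treatment == "sham"]
    hits = [v for v in vials if v.treatment == "hit"]
    assert {v.unit_id for v in shams}.isdisjoint({v.unit_id for v in hits})
    with pytest.raises(ConfigError):
        TwoGroupSimConfig(n_units_per_group=1)


def test_line_traits_identity_correlation_bound():
    cfg = LineTraitSimConfig(n_lines=2000, trait_names=("a", "b", "c"),
                             trait_means=(0, 0, 0), trait_sds=(1, 1, 1),
                             correlation_matrix=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
                             seed=3)
    tab, _ = generate_line_traits(cfg)
    for tx, ty in (("a", "b"), ("a", "c"), ("b", "c")):
        r = np.corrcoef(tab.trait_values(tx), tab.trait_values(ty))[0, 1]
        assert abs(r) < 0.08                    # ~3/sqrt(n)


def test_line_traits_perfect_anticorrelation_exact():
    cfg = LineTraitSimConfig(n_lines=60, trait_names=("a", "b"),
                             trait_means=(0, 0), trait_sds=(1, 1),
                             correlation_matrix=((1.0, -1.0), (-1.0, 1.0)), seed=4)
    tab, _ = generate_line_traits(cfg)
    r = np.corrcoef(tab.trait_values("a"), tab.trait_values("b"))[0, 1]
    assert r == pytest.approx(-1.0, abs=1e-9)


def test_line_traits_non_psd_matrix_names_eigenvalue():
    with pytest.raises(ConfigError, match="eigenvalue"):
        LineTraitSimConfig(n_lines=10, trait_names=("a", "b", "c"),
                           trait_means=(0, 0, 0), trait_sds=(1, 1, 1),
                           correlation_matrix=((1, 0.9, -0.9), (0.9, 1, 0.9),
                                               (-0.9, 0.9, 1)))


def test_line_traits_bootstrap_ci_coverage_at_viability_scale():
    """Target r = -0.28 at n = 49: bootstrap CI covers truth in ~95% of replicates."""
    cfg = LineTraitSimConfig(
        n_lines=49, trait_names=("mi", "viability"), trait_means=(25.0, 80.0),
        trait_sds=(12.0, 10.0), correlation_matrix=((1.0, -0.28), (-0.28, 1.0)))
    covered = 0
    n_rep = 200
    for k in range(n_rep):
        tab, _ = generate_line_traits(dataclasses.replace(cfg, seed=k))
        x, y = tab.complete_pairs("mi", "viability")
        est = bootstrap_correlation(x, y, n_reps=1000, seed=k)
        covered += est.boot_ci_low <= -0.28 <= est.boot_ci_high
    assert 0.88 <= covered / n_rep <= 0.99       # ~95% with generous MC slack
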