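"""Synthetic family-structured binomial mortality data with known truth.

Generators emulate the three experimental layouts of the trauma-mortality
study so that every estimator in the package can be tested against a known
ground truth:

* ``generate_half_sib`` — a paternal half-sib breeding design: each sire is
  mated to several dams, each dam's offspring (Poisson-distributed in number)
  are split into one trauma (hit) vial and one sham vial, and deaths are
  binomial with a logit-scale linear predictor carrying sire and dam random
  effects plus a block effect.  Sham mortality is a shared constant: the
  mortality index subtracts the sham baseline, so family effects act on the
  hit arm only.
* ``generate_two_group`` — two-group contrasts (inbred/outbred,
  mutagenized/control, low/high larval diet) with per-unit logit shifts, in
  either a paired (per-unit sham vial) or a pooled-sham layout, optionally
  with Normal dry-mass samples.
* ``generate_line_traits`` — multivariate-normal line-level trait tables
  with a specified correlation matrix (DGRP-style).

Every dataset carries a :class:`SimTruth` with the generating configuration,
the realized random effects, and (for mortality designs, computed lazily by
large-sample Monte-Carlo) the implied variance components on the MI scale.
Randomness uses counter-based Philox streams keyed on ``(seed, stream)`` so
output is reproducible independent of generation order.

Default parameter values mirror the study designs: 55 sires with 3 dams each
(of which roughly a fifth produce no offspring), ~79 offspring per dam split
across the two arms, two blocks; two-group designs with 34 units per group
and ~49 flies per MI measure.  Sham mortality is set to 2% — the studies
treat it as a small nuisance baseline without reporting its magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import cached_property, lru_cache
from typing import Any, Sequence

import numpy as np
from scipy.special import expit, logit

from .core_data_io import LineTraitTable, MassRecord, VialCount
import pandas as pd

_DATA_STREAM = 0
_TRUTH_STREAM = 1


def _rng(seed: int | None, stream: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([seed or 0, stream])))


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


# ---------------------------------------------------------------------------
# configurations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HalfSibSimConfig:
    """Half-sib design generator settings (defaults emulate the breeding study)."""

    n_sires: int = 55
    dams_per_sire: int | tuple[int, int] = 3
    dam_dropout: float = 0.19          # P(a dam yields no offspring)
    offspring_mean: float = 79.0       # Poisson mean offspring per dam (both arms)
    p_sham: float = 0.02               # shared sham baseline mortality
    mu_hit: float = 2.63               # logit-scale added trauma mortality
    sigma_sire: float = 0.305          # logit-scale sire SD
    sigma_dam: float = 0.53            # logit-scale dam SD
    n_blocks: int = 2
    block_shift: float = 0.2           # logit-scale block effect
    seed: int | None = None

    def __post_init__(self):
        if self.n_sires < 1:
            raise ConfigError("n_sires must be >= 1")
        if self.offspring_mean <= 0:
            raise ConfigError("offspring_mean must be > 0")
        if not 0 <= self.p_sham <= 1:
            raise ConfigError("p_sham must be a probability")
        if not 0 <= self.dam_dropout < 1:
            raise ConfigError("dam_dropout must be in [0, 1)")
        if self.sigma_sire < 0 or self.sigma_dam < 0:
            raise ConfigError("sigma_sire and sigma_dam must be >= 0")
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")


@dataclass(frozen=True)
class TwoGroupSimConfig:
    """Two-group contrast generator settings (defaults emulate the inbreeding study)."""

    n_units_per_group: int = 34
    flies_per_vial: int | tuple[int, int] = (19, 25)
    p_sham: float = 0.02
    p_hit_a: float = 0.087             # hit-arm mortality, group a (mean MI ~ 6.7)
    p_hit_b: float = 0.087
    unit_sd: float = 0.8               # logit-scale between-unit SD
    layout: str = "paired"             # "paired" or "pooled"
    n_sham_vials: int | None = None    # pooled layout only; default n_units_per_group
    group_names: tuple[str, str] = ("group_a", "group_b")
    mass_mean_a: float | None = None   # optional Normal dry-mass samples (mg)
    mass_mean_b: float | None = None
    mass_sd_a: float = 0.03
    mass_sd_b: float = 0.03
    n_mass_per_group: int = 51
    mass_sex: str = "female"
    seed: int | None = None

    def __post_init__(self):
        if self.n_units_per_group < 2:
            raise ConfigError("n_units_per_group must be >= 2")
        for p in (self.p_sham, self.p_hit_a, self.p_hit_b):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.unit_sd < 0:
            raise ConfigError("unit_sd must be >= 0")
        if self.layout not in ("paired", "pooled"):
            raise ConfigError("layout must be 'paired' or 'pooled'")


@dataclass(frozen=True)
class LineTraitSimConfig:
    """Multivariate-normal line-trait table settings (defaults are DGRP-like)."""

    n_lines: int = 169
    trait_names: tuple[str, ...] = ("mi", "viability", "fecundity", "lifespan")
    trait_means: tuple[float, ...] = (25.0, 80.0, 1500.0, 55.0)
    trait_sds: tuple[float, ...] = (12.0, 10.0, 400.0, 9.0)
    correlation_matrix: tuple[tuple[float, ...], ...] = (
        (1.00, -0.28, -0.20, -0.20),
        (-0.28, 1.00, 0.20, 0.20),
        (-0.20, 0.20, 1.00, 0.30),
        (-0.20, 0.20, 0.30, 1.00),
    )
    seed: int | None = None

    def __post_init__(self):
        k = len(self.trait_names)
        if not (len(self.trait_means) == len(self.trait_sds) == k):
            raise ConfigError("trait_names, trait_means and trait_sds lengths differ")
        R = np.asarray(self.correlation_matrix, dtype=float)
        if R.shape != (k, k):
            raise ConfigError(f"correlation matrix must be {k}x{k}")
        if not np.allclose(R, R.T):
            raise ConfigError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigError("correlation matrix must have unit diagonal")
        w = np.linalg.eigvalsh(R)
        if w.min() < -1e-8:
            raise ConfigError(
                f"correlation matrix is not positive semi-definite "
                f"(smallest eigenvalue {w.min():.3e})")


@dataclass
class SimTruth:
    """Ground truth attached to every synthetic dataset.

    ``mi_scale`` (mortality designs only) maps the logit-scale configuration
    to the MI scale by large-sample Monte-Carlo — the logit-to-MI mapping is
    nonlinear, so these values are approximate by construction and flagged so.
    """

    config: Any
    realized: dict = field(default_factory=dict)

    @cached_property
    def mi_scale(self) -> dict:
        cfg = replace(self.config, seed=None)     # truth is seed-independent
        if isinstance(cfg, HalfSibSimConfig):
            return dict(_half_sib_mi_truth(cfg))
        if isinstance(cfg, TwoGroupSimConfig):
            return dict(_two_group_mi_truth(cfg))
        raise TypeError("mi_scale truth is defined for mortality designs only")


# ---------------------------------------------------------------------------
# half-sib generator
# ---------------------------------------------------------------------------

def _dam_counts(cfg, rng, n_sires) -> np.ndarray:
    if isinstance(cfg.dams_per_sire, tuple):
        lo, hi = cfg.dams_per_sire
        return rng.integers(lo, hi + 1, size=n_sires)
    return np.full(n_sires, int(cfg.dams_per_sire))


def generate_half_sib(config: HalfSibSimConfig) -> tuple[list[VialCount], SimTruth]:
    """Generate vial counts for a paternal half-sib design.

    For sire i, s_i ~ N(0, sigma_sire^2); for dam j of sire i,
    d_ij ~ N(0, sigma_dam^2).  Offspring n_ij ~ Poisson(offspring_mean) are
    split as evenly as possible between one hit and one sham vial (the odd
    fly goes to the hit vial).  Sham deaths ~ Binomial(n_sham, p_sham); hit
    deaths ~ Binomial(n_hit, expit(logit(p_sham) + mu_hit + s_i + d_ij +
    block)).  Dams with no offspring (dropout or a zero Poisson draw) are
    dropped, mirroring dams that produced no offspring in the experiment.
    """
    cfg = config
    rng = _rng(cfg.seed, _DATA_STREAM)
    sire_eff = rng.normal(0.0, cfg.sigma_sire, size=cfg.n_sires)
    n_dams = _dam_counts(cfg, rng, cfg.n_sires)
    base = logit(cfg.p_sham) + cfg.mu_hit
    vials: list[VialCount] = []
    dam_effects: dict[str, float] = {}
    width = len(str(cfg.n_sires))
    for i in range(cfg.n_sires):
        sire_id = f"S{i + 1:0{width}d}"
        block_idx = i % cfg.n_blocks
        block = f"B{block_idx + 1}"
        block_term = cfg.block_shift * block_idx
        for j in range(n_dams[i]):
            d_ij = rng.normal(0.0, cfg.sigma_dam)
            dropped = rng.random() < cfg.dam_dropout
            n_off = int(rng.poisson(cfg.offspring_mean))
            if dropped or n_off == 0:
                continue
            dam_id = f"{sire_id}D{j + 1}"
            dam_effects[dam_id] = d_ij
            n_hit = (n_off + 1) // 2
            n_sham = n_off // 2
            p_hit = float(expit(base + sire_eff[i] + d_ij + block_term))
            dead_hit = int(rng.binomial(n_hit, p_hit))
            dead_sham = int(rng.binomial(n_sham, cfg.p_sham)) if n_sham else 0
            for treatment, nf, nd in (("hit", n_hit, dead_hit),
                                      ("sham", n_sham, dead_sham)):
                vials.append(VialCount(study_id="halfsib", block=block,
                                       group_id=sire_id, unit_id=dam_id,
                                       treatment=treatment, n_flies=nf, n_dead=nd))
    truth = SimTruth(config=cfg, realized={
        "sire_effects": {f"S{i + 1:0{width}d}": float(sire_eff[i])
                         for i in range(cfg.n_sires)},
        "dam_effects": dam_effects,
    })
    return vials, truth


@lru_cache(maxsize=32)
def _half_sib_mi_truth(cfg: HalfSibSimConfig, n_mc_sires: int = 100_000,
                       n_mc_dams: int = 40) -> dict:
    """Implied MI-scale variance components by Monte-Carlo (approximate).

    Sire component: variance over sires of the expected dam-level MI
    (block-centered, both blocks weighted equally).  Residual: dam-effect
    variance of the expected MI plus the average binomial sampling variance
    at Poisson family sizes.  The truth stream is keyed on the structural
    parameters only, so configs differing only in ``seed`` share one truth.
    """
    rng = _rng(0, _TRUTH_STREAM)
    s = rng.normal(0.0, cfg.sigma_sire, size=(n_mc_sires, 1))
    d = rng.normal(0.0, cfg.sigma_dam, size=(n_mc_sires, n_mc_dams))
    eta = logit(cfg.p_sham) + cfg.mu_hit + s + d
    blocks = np.arange(cfg.n_blocks) * cfg.block_shift
    mean_mi = 0.0
    mi_centered = np.zeros_like(eta)
    for b in blocks:
        p = expit(eta + b)
        mi_b = 100.0 * (p - cfg.p_sham)
        mean_mi += mi_b.mean() / len(blocks)
        mi_centered += (mi_b - mi_b.mean()) / len(blocks)
    sire_means = mi_centered.mean(axis=1)
    within = mi_centered.var(axis=1, ddof=1)
    # correct the MC noise that within-sire sampling adds to var(sire_means)
    sigma2_sire = float(sire_means.var(ddof=1) - within.mean() / n_mc_dams)
    # binomial sampling variance at realized family sizes
    n_off = rng.poisson(cfg.offspring_mean, size=eta.shape)
    keep = n_off > 1
    n_hit = (n_off + 1) // 2
    n_sham = np.maximum(n_off // 2, 1)
    p_mid = expit(eta + blocks.mean())
    binom = 1e4 * (p_mid * (1 - p_mid) / n_hit
                   + cfg.p_sham * (1 - cfg.p_sham) / n_sham)
    sigma2_binom = float(binom[keep].mean())
    sigma2_resid = float(within.mean()) + sigma2_binom
    total = sigma2_sire + sigma2_resid
    va = 4.0 * sigma2_sire
    mean_mi = float(mean_mi)
    return {
        "mean_mi": float(mean_mi),
        "sigma2_sire": sigma2_sire,
        "sigma2_resid": sigma2_resid,
        "icc": sigma2_sire / total,
        "va": va,
        "vp": total,
        "h2": va / total,
        "cva": 100.0 * math.sqrt(max(va, 0.0)) / mean_mi,
        "approximate": True,
        "n_mc": n_mc_sires * n_mc_dams,
    }


# ---------------------------------------------------------------------------
# two-group generator
# ---------------------------------------------------------------------------

def _vial_size(cfg, rng) -> int:
    if isinstance(cfg.flies_per_vial, tuple):
        lo, hi = cfg.flies_per_vial
        return int(rng.integers(lo, hi + 1))
    return int(cfg.flies_per_vial)


def generate_two_group(config: TwoGroupSimConfig
                       ) -> tuple[list[VialCount], list[MassRecord], SimTruth]:
    """Generate a two-group contrast (paired or pooled-sham layout).

    Each unit in group g draws a logit shift u ~ N(0, unit_sd^2) applied to
    the group's hit-arm mortality.  Paired layout: one hit and one sham vial
    per unit.  Pooled layout: one hit vial per unit plus ``n_sham_vials``
    stand-alone sham vials per group.  When mass means are configured,
    Normal dry-mass samples are generated per group as well.
    """
    cfg = config
    rng = _rng(cfg.seed, _DATA_STREAM)
    vials: list[VialCount] = []
    masses: list[MassRecord] = []
    unit_shifts: dict[str, float] = {}
    for g, (gname, p_hit) in enumerate(zip(cfg.group_names,
                                           (cfg.p_hit_a, cfg.p_hit_b))):
        eta0 = logit(p_hit)
        for u in range(cfg.n_units_per_group):
            unit_id = f"{gname}_U{u + 1:03d}"
            shift = rng.normal(0.0, cfg.unit_sd)
            unit_shifts[unit_id] = shift
            p = float(expit(eta0 + shift))
            n_hit = _vial_size(cfg, rng)
            vials.append(VialCount(study_id="twogroup", block="B1",
                                   group_id=gname, unit_id=unit_id,
                                   treatment="hit", n_flies=n_hit,
                                   n_dead=int(rng.binomial(n_hit, p))))
            if cfg.layout == "paired":
                n_sham = _vial_size(cfg, rng)
                vials.append(VialCount(study_id="twogroup", block="B1",
                                       group_id=gname, unit_id=unit_id,
                                       treatment="sham", n_flies=n_sham,
                                       n_dead=int(rng.binomial(n_sham, cfg.p_sham))))
        if cfg.layout == "pooled":
            n_sham_vials = cfg.n_sham_vials or cfg.n_units_per_group
            for v in range(n_sham_vials):
                n_sham = _vial_size(cfg, rng)
                vials.append(VialCount(study_id="twogroup", block="B1",
                                       group_id=gname,
                                       unit_id=f"{gname}_SH{v + 1:03d}",
                                       treatment="sham", n_flies=n_sham,
                                       n_dead=int(rng.binomial(n_sham, cfg.p_sham))))
        mass_mean = (cfg.mass_mean_a, cfg.mass_mean_b)[g]
        if mass_mean is not None:
            sd = (cfg.mass_sd_a, cfg.mass_sd_b)[g]
            draws = np.abs(rng.normal(mass_mean, sd, size=cfg.n_mass_per_group))
            masses.extend(MassRecord(group_id=gname, sex=cfg.mass_sex,
                                     dry_mass=float(m)) for m in draws)
    truth = SimTruth(config=cfg, realized={"unit_shifts": unit_shifts})
    return vials, masses, truth


@lru_cache(maxsize=32)
def _two_group_mi_truth(cfg: TwoGroupSimConfig, n_mc: int = 400_000) -> dict:
    rng = _rng(0, _TRUTH_STREAM)
    out: dict = {"approximate": True, "n_mc": n_mc}
    for gname, p_hit in zip(cfg.group_names, (cfg.p_hit_a, cfg.p_hit_b)):
        u = rng.normal(0.0, cfg.unit_sd, size=n_mc)
        p = expit(logit(p_hit) + u)
        mi = 100.0 * (p - cfg.p_sham)
        out[f"mean_mi_{gname}"] = float(mi.mean())
        out[f"sd_mi_{gname}"] = float(mi.std(ddof=1))
    a, b = cfg.group_names
    out["mean_mi_diff"] = out[f"mean_mi_{b}"] - out[f"mean_mi_{a}"]
    return out


# ---------------------------------------------------------------------------
# line-trait generator
# ---------------------------------------------------------------------------

def generate_line_traits(config: LineTraitSimConfig) -> tuple[LineTraitTable, SimTruth]:
    """Multivariate-normal line means with the configured correlation matrix.

    Uses an eigen-factorization of the correlation matrix (handles exactly
    singular PSD matrices, e.g. a perfect -1 correlation, that a Cholesky
    factorization would reject).
    """
    cfg = config
    rng = _rng(cfg.seed, _DATA_STREAM)
    k = len(cfg.trait_names)
    R = np.asarray(cfg.correlation_matrix, dtype=float)
    w, V = np.linalg.eigh(R)
    L = V * np.sqrt(np.maximum(w, 0.0))
    z = rng.standard_normal(size=(cfg.n_lines, k))
    X = z @ L.T
    means = np.asarray(cfg.trait_means, dtype=float)
    sds = np.asarray(cfg.trait_sds, dtype=float)
    data = means + X * sds
    df = pd.DataFrame(data, columns=list(cfg.trait_names))
    df.insert(0, "line_id", [f"L{i + 1:04d}" for i in range(cfg.n_lines)])
    table = LineTraitTable(df)
    truth = SimTruth(config=cfg, realized={
        "trait_means": list(means), "trait_sds": list(sds),
        "correlation_matrix": R.tolist()})
    return table, truth
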