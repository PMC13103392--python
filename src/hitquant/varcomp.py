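"""REML variance components for the half-sib design, with an ANOVA oracle.

The response is dam-level MI (one value per dam), modelled as the unbalanced
one-way random-effects model

    MI_ij = mu + block_b(ij) + u_i + e_ij,   u_i ~ N(0, s2_sire),
                                             e_ij ~ N(0, s2_resid),

with sire i as the random grouping factor and the experimental block as an
optional fixed effect.  Because there is one MI per dam, dam variance is
confounded with the residual and is not modelled separately.

In a half-sib design the additive genetic variance is VA = 4 * s2_sire
(sires transmit a quarter of the additive variance to each offspring, and
sire family means expose a quarter of VA).  Phenotypic variance is taken as
VP = s2_sire + s2_resid from the same dam-level model, so the reported h2 =
VA / VP can exceed 1; the coefficient of additive genetic variation is
CVA = 100 * sqrt(VA) / grand_mean.

Restricted likelihood is profiled over the variance ratio
gamma = s2_sire / s2_resid using the closed-form compound-symmetry inverse
per sire family, so each evaluation is O(n).  The sire term is tested by a
likelihood-ratio test against the gamma = 0 model with identical fixed
effects, referred to chi-square with df = 1; the 50:50 boundary-mixture
p-value is also reported as a diagnostic (the plain chi2_1 reference is
conservative when the null puts the parameter on the boundary).

``anova_varcomp`` provides the independent expected-mean-squares
(method-of-moments) estimator for the same model without fixed effects
beyond the intercept; on balanced designs with an interior optimum it agrees
exactly with REML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .core_data_io import MIRecord

# profile-search bracket for gamma = s2_sire / s2_resid
_LOG_GAMMA_LO = math.log(1e-8)
_LOG_GAMMA_HI = math.log(1e4)
_GRID_POINTS = 61
_XATOL = 1e-12


class DegenerateDataError(ValueError):
    """The data carry no usable variation for the requested fit."""


@dataclass
class AnovaVarComp:
    """Expected-mean-squares (method-of-moments) one-way variance components."""

    ms_among: float
    ms_within: float
    n0: float                     # effective per-group size for unbalanced data
    sigma2_s_mom: float           # may be negative before truncation
    sigma2_e_mom: float
    truncated: bool               # True when a negative sigma2_s was clamped to 0
    n_groups: int
    n_total: int

    @property
    def sigma2_s(self) -> float:
        return max(self.sigma2_s_mom, 0.0)


@dataclass
class VarCompEstimate:
    """REML fit of the one-way sire model plus derived quantitative genetics."""

    sigma2_sire: float
    sigma2_resid: float
    grand_mean: float
    fixed_effects: dict[str, float]
    va: float
    vp: float
    h2: float
    cva: float
    log_reml_full: float
    log_reml_null: float
    chi2: float
    df: int
    p: float
    p_boundary_mixture: float     # 0.5*chi2_0 + 0.5*chi2_1 reference (diagnostic)
    converged: bool
    n_sires: int
    n_dams: int

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["fixed_effects"] = dict(self.fixed_effects)
        return d


@dataclass
class QuantGen:
    va: float
    vp: float
    h2: float
    cva: float


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _prepare(mi: Sequence[float], sire: Sequence[str],
             block: Sequence[str] | None, include_block: bool):
    y = np.asarray(mi, dtype=float)
    sire = np.asarray([str(s) for s in sire])
    if y.ndim != 1 or len(y) != len(sire):
        raise ValueError("mi and sire must be equal-length 1-d sequences")
    if not np.all(np.isfinite(y)):
        raise ValueError("mi values must be finite")
    sires, sire_codes = np.unique(sire, return_inverse=True)
    if len(sires) < 2:
        raise DegenerateDataError("at least two sires are required")
    order = np.argsort(sire_codes, kind="stable")
    y = y[order]
    codes = sire_codes[order]
    sizes = np.bincount(codes)
    # fixed-effect design: intercept + block contrasts (treatment coding)
    names = ["intercept"]
    X = [np.ones(len(y))]
    if include_block and block is not None:
        blk = np.asarray([str(b) for b in block])[order]
        levels = sorted(set(blk))
        for lev in levels[1:]:
            X.append((blk == lev).astype(float))
            names.append(f"block[{lev}]")
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDataError("fixed-effect design matrix is rank deficient")
    return y, codes, sizes, X, names, sires


def _reml_loglik(gamma: float, y: np.ndarray, codes: np.ndarray,
                 sizes: np.ndarray, X: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Profiled restricted log-likelihood at variance ratio gamma.

    Returns (loglik, sigma2_e_hat, beta_hat).  Uses the compound-symmetry
    identity (I + gamma*J)^{-1} = I - (gamma/(1+gamma*n)) J per sire family.
    """
    n, p = X.shape
    c = gamma / (1.0 + gamma * sizes)               # per-group shrinkage
    Sx = np.zeros((len(sizes), p))
    for j in range(p):
        Sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=len(sizes))
    Sy = np.bincount(codes, weights=y, minlength=len(sizes))
    XtWX = X.T @ X - (Sx * c[:, None]).T @ Sx
    XtWy = X.T @ y - Sx.T @ (c * Sy)
    ytWy = y @ y - c @ (Sy ** 2)
    beta = np.linalg.solve(XtWX, XtWy)
    quad = ytWy - XtWy @ beta
    nmp = n - p
    if quad <= 0:
        raise DegenerateDataError("zero residual variation (all MI identical given "
                                  "the fixed effects)")
    sigma2_e = quad / nmp
    logdet_v = float(np.sum(np.log1p(gamma * sizes)))
    sign, logdet_x = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise DegenerateDataError("X'V^{-1}X not positive definite")
    ll = -0.5 * (nmp * (math.log(2 * math.pi) + 1.0 + math.log(sigma2_e))
                 + logdet_v + logdet_x)
    return ll, sigma2_e, beta


def profile_reml_loglik(gamma: float, mi: Sequence[float], sire: Sequence[str],
                        block: Sequence[str] | None = None,
                        include_block: bool = True) -> float:
    """Restricted log-likelihood at a given variance ratio (for audits)."""
    y, codes, sizes, X, _, _ = _prepare(mi, sire, block, include_block)
    return _reml_loglik(max(gamma, 0.0), y, codes, sizes, X)[0]


# ---------------------------------------------------------------------------
# public fits
# ---------------------------------------------------------------------------

def fit_sire_model(mi: Sequence[float], sire: Sequence[str],
                   block: Sequence[str] | None = None,
                   include_block: bool = True,
                   cva_weights: Sequence[float] | None = None) -> VarCompEstimate:
    """REML fit of the one-way sire model on dam-level MI.

    Parameters
    ----------
    mi, sire, block
        Parallel sequences: one MI value per dam, its sire label, and
        (optionally) its experimental block.
    include_block
        Fit block as a fixed effect (ignored when ``block`` is None).
    cva_weights
        Optional weights (e.g. family sizes) for the grand mean used in CVA;
        default is the unweighted mean of dam-level MI.
    """
    y, codes, sizes, X, names, sires = _prepare(mi, sire, block, include_block)

    def crit(log_gamma: float) -> float:
        return -_reml_loglik(math.exp(log_gamma), y, codes, sizes, X)[0]

    ll0, s2e0, _ = _reml_loglik(0.0, y, codes, sizes, X)
    grid = np.linspace(_LOG_GAMMA_LO, _LOG_GAMMA_HI, _GRID_POINTS)
    vals = np.array([crit(g) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(crit, bounds=(lo, hi), method="bounded",
                                   options={"xatol": _XATOL})
    converged = bool(res.success)
    ll_int = -float(res.fun)
    if ll_int > ll0:
        gamma = math.exp(float(res.x))
        ll_full, sigma2_e, beta = _reml_loglik(gamma, y, codes, sizes, X)
        sigma2_s = gamma * sigma2_e
    else:                                           # boundary solution
        gamma = 0.0
        ll_full, sigma2_e, beta = ll0, s2e0, _reml_loglik(0.0, y, codes, sizes, X)[2]
        sigma2_s = 0.0

    chi2 = max(0.0, 2.0 * (ll_full - ll0))
    p = float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    p_mix = 0.5 * float(stats.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0

    if cva_weights is not None:
        w = np.asarray(cva_weights, dtype=float)
        if len(w) != len(mi):
            raise ValueError("cva_weights must match the number of MI records")
        grand_mean = float(np.average(np.asarray(mi, dtype=float), weights=w))
    else:
        grand_mean = float(np.mean(y))

    qg = derive_quantgen(sigma2_s, sigma2_e, grand_mean)
    return VarCompEstimate(
        sigma2_sire=float(sigma2_s), sigma2_resid=float(sigma2_e),
        grand_mean=grand_mean,
        fixed_effects={n: float(b) for n, b in zip(names, beta)},
        va=qg.va, vp=qg.vp, h2=qg.h2, cva=qg.cva,
        log_reml_full=float(ll_full), log_reml_null=float(ll0),
        chi2=float(chi2), df=1, p=p, p_boundary_mixture=p_mix,
        converged=converged, n_sires=len(sires), n_dams=len(y))


def fit_sire_model_records(records: Sequence[MIRecord],
                           include_block: bool = True,
                           cva_weighted: bool = False) -> VarCompEstimate:
    """Convenience wrapper: fit from MIRecords (sire = group_id, dam = unit_id)."""
    mi = [r.mi for r in records]
    sire = [r.group_id for r in records]
    blocks = [r.block for r in records]
    have_blocks = include_block and any(b for b in blocks)
    weights = [r.n_hit + r.n_sham for r in records] if cva_weighted else None
    return fit_sire_model(mi, sire, block=blocks if have_blocks else None,
                          include_block=have_blocks, cva_weights=weights)


def anova_varcomp(mi: Sequence[float], sire: Sequence[str]) -> AnovaVarComp:
    """Expected-mean-squares estimator for the unbalanced one-way model.

    n0 = (N - sum(n_i^2)/N) / (a - 1); sigma2_s = (MS_among - MS_within)/n0.
    Negative moment estimates are reported and flagged, and clamped to zero
    in ``sigma2_s``.
    """
    y = np.asarray(mi, dtype=float)
    sire = np.asarray([str(s) for s in sire])
    groups, codes = np.unique(sire, return_inverse=True)
    a = len(groups)
    if a < 2:
        raise DegenerateDataError("at least two sires are required")
    N = len(y)
    sizes = np.bincount(codes).astype(float)
    sums = np.bincount(codes, weights=y)
    means = sums / sizes
    grand = float(np.mean(y))
    ss_among = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(np.sum((y - means[codes]) ** 2))
    ms_among = ss_among / (a - 1)
    if N == a:
        raise DegenerateDataError("no within-sire replication (one dam per sire)")
    ms_within = ss_within / (N - a)
    n0 = (N - float(np.sum(sizes ** 2)) / N) / (a - 1)
    s2s = (ms_among - ms_within) / n0
    return AnovaVarComp(ms_among=ms_among, ms_within=ms_within, n0=n0,
                        sigma2_s_mom=s2s, sigma2_e_mom=ms_within,
                        truncated=s2s < 0, n_groups=a, n_total=N)


def lrt_sire_variance(mi: Sequence[float], sire: Sequence[str],
                      block: Sequence[str] | None = None,
                      include_block: bool = True) -> tuple[float, int, float]:
    """Likelihood-ratio test of s2_sire = 0: (chi2, df, p) with df = 1."""
    fit = fit_sire_model(mi, sire, block=block, include_block=include_block)
    return fit.chi2, fit.df, fit.p


def derive_quantgen(sigma2_s: float, sigma2_e: float, grand_mean: float) -> QuantGen:
    """VA, VP, h2 and CVA from the fitted components and the grand mean MI.

    VA = 4*sigma2_s (half-sib design); VP = sigma2_s + sigma2_e; h2 = VA/VP;
    CVA = 100*sqrt(VA)/grand_mean.  With sigma2_s = 0 all of VA, h2 and CVA
    are 0; a zero grand mean with positive VA leaves CVA undefined.
    """
    if sigma2_s < 0 or sigma2_e < 0:
        raise ValueError("variance components must be non-negative")
    va = 4.0 * sigma2_s
    vp = sigma2_s + sigma2_e
    h2 = va / vp if vp > 0 else 0.0
    if va == 0.0:
        cva = 0.0
    elif grand_mean == 0.0:
        raise ZeroDivisionError("CVA undefined: grand mean MI is zero")
    else:
        cva = 100.0 * math.sqrt(va) / grand_mean
    return QuantGen(va=va, vp=vp, h2=h2, cva=cva)
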