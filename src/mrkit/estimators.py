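"""Causal-effect estimators for two-sample MR over harmonised instruments.

All estimators operate on the Wald-ratio decomposition: per SNP j the
instrument supplies an exposure effect beta_x_j (SE sigma_x_j) and an
outcome effect beta_y_j (SE sigma_y_j) aligned to the same allele, and the
per-SNP causal estimate is the ratio beta_y_j / beta_x_j.

* ``ivw_mre`` — inverse-variance-weighted regression of beta_y on beta_x
  through the origin, with a multiplicative random-effects scale floored at
  1 so over-dispersion inflates the SE but under-dispersion never shrinks it.
* ``egger`` — the same weighted regression with an intercept; the intercept
  estimates directional pleiotropy, and inference uses a t distribution with
  J-2 degrees of freedom.
* ``weighted_median`` — consistent when at least half the weight comes from
  valid instruments; SE by parametric bootstrap.
* ``weighted_mode`` — consistent when the largest weight-cluster of ratios
  is valid; normal-kernel density with a modified Silverman bandwidth.

First-order Wald SEs (exposure-side uncertainty ignored) are used in all
weights; this rests on strong instruments (no-measurement-error, checked via
the F statistic).  A second-order option exists on :func:`wald_ratio`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .instruments import HarmonisedInstrument

__all__ = [
    "MREstimate",
    "EggerEstimate",
    "InsufficientInstrumentsError",
    "UndefinedRatioError",
    "wald_ratio",
    "ivw_mre",
    "egger",
    "weighted_median",
    "weighted_mode",
    "SD_EXPOSURE",
    "BINARY_EXPOSURE",
]

Z975 = float(stats.norm.ppf(0.975))

SD_EXPOSURE = "SD_EXPOSURE"
BINARY_EXPOSURE = "BINARY_EXPOSURE"


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested estimator."""


class UndefinedRatioError(ZeroDivisionError):
    """Wald ratio undefined because the exposure effect is zero."""


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate on the log scale, with its OR translation.

    ``theta`` is the effect per SD-unit (or, for binary exposures, per
    log-odds-unit) increase in the exposure; ``or_point`` is exp(theta).
    ``caveat`` flags binary-exposure estimates whose OR magnitude is
    reported for completeness only.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    scale: str = SD_EXPOSURE
    caveat: bool = False

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.method}: se must be positive")
        if not (self.ci_low < self.theta < self.ci_high):
            raise ValueError(f"{self.method}: CI must bracket theta")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.method}: pval must lie in (0, 1]")

    @property
    def or_point(self) -> float:
        return math.exp(self.theta)

    @property
    def or_low(self) -> float:
        return math.exp(self.ci_low)

    @property
    def or_high(self) -> float:
        return math.exp(self.ci_high)


@dataclass(frozen=True)
class EggerEstimate:
    """MR-Egger slope plus the pleiotropy-intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def _estimate(
    method: str,
    theta: float,
    se: float,
    n_snps: int,
    *,
    scale: str = SD_EXPOSURE,
    caveat: bool = False,
    df: int | None = None,
) -> MREstimate:
    """Build an MREstimate with normal (default) or t (df given) inference."""
    if df is None:
        q = Z975
        pval = 2.0 * stats.norm.sf(abs(theta) / se)
    else:
        q = float(stats.t.ppf(0.975, df))
        pval = 2.0 * stats.t.sf(abs(theta) / se, df)
    return MREstimate(
        method=method,
        theta=theta,
        se=se,
        ci_low=theta - q * se,
        ci_high=theta + q * se,
        pval=max(float(pval), 5e-324),
        n_snps=n_snps,
        scale=scale,
        caveat=caveat,
    )


def _arrays(instruments: Sequence[HarmonisedInstrument]):
    bx = np.array([i.beta_x for i in instruments], dtype=float)
    sx = np.array([i.se_x for i in instruments], dtype=float)
    by = np.array([i.beta_y for i in instruments], dtype=float)
    sy = np.array([i.se_y for i in instruments], dtype=float)
    return bx, sx, by, sy


def wald_ratio(
    inst: HarmonisedInstrument,
    *,
    second_order: bool = False,
    scale: str = SD_EXPOSURE,
    caveat: bool = False,
) -> MREstimate:
    """Single-SNP causal estimate beta_y/beta_x with a delta-method SE.

    The default first-order SE is se_y/|beta_x|; ``second_order=True`` adds
    the exposure-side term sqrt(se_y^2/beta_x^2 + beta_y^2 se_x^2/beta_x^4).
    """
    if inst.beta_x == 0:
        raise UndefinedRatioError(f"{inst.snp_id}: exposure effect is zero")
    theta = inst.beta_y / inst.beta_x
    if second_order:
        se = math.sqrt(
            inst.se_y**2 / inst.beta_x**2
            + inst.beta_y**2 * inst.se_x**2 / inst.beta_x**4
        )
    else:
        se = inst.se_y / abs(inst.beta_x)
    return _estimate("WALD", theta, se, 1, scale=scale, caveat=caveat)


def _ivw_point(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * bx * by) / np.sum(w * bx * bx))


def ivw_mre(
    instruments: Sequence[HarmonisedInstrument],
    *,
    scale: str = SD_EXPOSURE,
    caveat: bool = False,
) -> MREstimate:
    """Multiplicative random-effects IVW estimate.

    Weighted regression of beta_y on beta_x through the origin with weights
    w_j = se_y_j^-2.  The fixed-effect SE is inflated by the multiplicative
    scale phi = max(1, sqrt(Q/(J-1))), so heterogeneity widens the interval
    but can never narrow it.  P-values use the standard normal.
    """
    J = len(instruments)
    if J < 2:
        raise InsufficientInstrumentsError(
            f"IVW needs >= 2 instruments, got {J}; use wald_ratio for a single SNP"
        )
    bx, _, by, sy = _arrays(instruments)
    w = sy**-2.0
    theta = _ivw_point(bx, by, w)
    q = float(np.sum(w * (by - theta * bx) ** 2))
    se_fixed = float(np.sum(w * bx * bx)) ** -0.5
    phi = max(1.0, math.sqrt(q / (J - 1)))
    return _estimate("MRE_IVW", theta, se_fixed * phi, J, scale=scale, caveat=caveat)


def egger(
    instruments: Sequence[HarmonisedInstrument],
    *,
    scale: str = SD_EXPOSURE,
    caveat: bool = False,
) -> EggerEstimate:
    """MR-Egger regression: weighted fit of beta_y on beta_x with intercept.

    Instruments are first re-oriented so every exposure effect is
    non-negative (both betas negated where needed); the intercept then
    estimates the average directional pleiotropic effect.  Coefficient SEs
    carry the multiplicative scale phi = max(1, sqrt(RSS_w/(J-2))), and both
    p-values and the CI use the t distribution with J-2 df.
    """
    J = len(instruments)
    if J < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {J}")
    bx, _, by, sy = _arrays(instruments)
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = sy**-2.0
    X = sm.add_constant(bx, has_constant="add")
    fit = sm.WLS(by, X, weights=w).fit()
    intercept, slope = (float(c) for c in fit.params)
    rss_w = float(np.sum(w * fit.resid**2))
    phi = max(1.0, math.sqrt(rss_w / (J - 2)))
    se_unscaled = np.sqrt(np.diag(fit.normalized_cov_params))
    se_int, se_slope = (float(s) * phi for s in se_unscaled)
    slope_est = _estimate("EGGER", slope, se_slope, J, scale=scale, caveat=caveat, df=J - 2)
    intercept_p = max(float(2.0 * stats.t.sf(abs(intercept) / se_int, J - 2)), 5e-324)
    return EggerEstimate(
        slope=slope_est,
        intercept=intercept,
        intercept_se=se_int,
        intercept_pval=intercept_p,
    )


def _ratio_inputs(bx: np.ndarray, by: np.ndarray, sy: np.ndarray):
    theta = by / bx
    w = (sy / np.abs(bx)) ** -2.0
    return theta, w / w.sum()


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    """Cumulative-weight interpolation at the 50% midpoint."""
    order = np.argsort(theta, kind="stable")
    t, ww = theta[order], w[order] / w[order].sum()
    s = np.cumsum(ww)
    p = s - ww / 2.0
    return float(np.interp(0.5, p, t))


def _weighted_mad(theta: np.ndarray, w: np.ndarray) -> float:
    med = _weighted_median_point(theta, w)
    return _weighted_median_point(np.abs(theta - med), w)


def _weighted_mode_point(theta: np.ndarray, w: np.ndarray, phi: float, grid_size: int = 4096) -> float:
    """Argmax of the weight-weighted normal-kernel density of the ratios."""
    w = w / w.sum()
    mean = float(np.sum(w * theta))
    sd = math.sqrt(max(float(np.sum(w * (theta - mean) ** 2)), 0.0))
    mad = _weighted_mad(theta, w) * 1.4826
    h = phi * 0.9 * min(sd, mad) * len(theta) ** (-0.2)
    if h <= 0:
        # degenerate spread: return the value carrying the most weight
        vals, inv = np.unique(theta, return_inverse=True)
        return float(vals[np.argmax(np.bincount(inv, weights=w))])
    grid = np.linspace(theta.min(), theta.max(), grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w
    return float(grid[np.argmax(dens)])


def _bootstrap_se(
    point,  # callable(theta, w) -> float
    bx: np.ndarray,
    sx: np.ndarray,
    by: np.ndarray,
    sy: np.ndarray,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: redraw effects from their normals, re-estimate."""
    rng = np.random.default_rng(seed)
    est = np.empty(n_boot)
    for b in range(n_boot):
        bxb = rng.normal(bx, sx)
        byb = rng.normal(by, sy)
        bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
        theta, w = _ratio_inputs(bxb, byb, sy)
        est[b] = point(theta, w)
    sd = float(np.std(est, ddof=1))
    # degenerate resamples: keep the SE strictly positive at float resolution
    return max(sd, 1e-12 * max(1.0, abs(float(np.mean(est)))))


def weighted_median(
    instruments: Sequence[HarmonisedInstrument],
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    scale: str = SD_EXPOSURE,
    caveat: bool = False,
) -> MREstimate:
    """Weighted-median estimator over the per-SNP Wald ratios.

    Ratios are weighted by inverse first-order Wald variance; the estimate
    interpolates the ratio at cumulative weight 0.5 and is consistent if
    valid instruments carry at least half the total weight.  The SE comes
    from a parametric bootstrap (``n_boot`` replicates, caller-supplied
    ``seed``), with normal-based CI and p-value.
    """
    J = len(instruments)
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 instruments, got {J}")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap SE")
    bx, sx, by, sy = _arrays(instruments)
    theta, w = _ratio_inputs(bx, by, sy)
    point = _weighted_median_point(theta, w)
    se = _bootstrap_se(_weighted_median_point, bx, sx, by, sy, n_boot, seed)
    return _estimate("WME", point, se, J, scale=scale, caveat=caveat)


def weighted_mode(
    instruments: Sequence[HarmonisedInstrument],
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    scale: str = SD_EXPOSURE,
    caveat: bool = False,
) -> MREstimate:
    """Weighted-mode estimator over the per-SNP Wald ratios.

    The mode of the inverse-variance-weighted normal-kernel density of the
    ratios, with bandwidth h = phi * 0.9 * min(weighted SD, 1.4826 *
    weighted MAD) * J^(-1/5) (modified Silverman rule; ``phi`` rescales it).
    Consistent if the largest cluster of ratios comes from valid
    instruments.  SE by parametric bootstrap as for the weighted median.
    """
    J = len(instruments)
    if J < 3:
        raise InsufficientInstrumentsError(f"weighted mode needs >= 3 instruments, got {J}")
    if phi <= 0:
        raise ValueError("phi must be positive")
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if seed is None:
        raise ValueError("a seed is required for the bootstrap SE")
    bx, sx, by, sy = _arrays(instruments)
    theta, w = _ratio_inputs(bx, by, sy)
    point = _weighted_mode_point(theta, w, phi)
    se = _bootstrap_se(
        lambda t, ww: _weighted_mode_point(t, ww, phi), bx, sx, by, sy, n_boot, seed
    )
    return _estimate("WMO", point, se, J, scale=scale, caveat=caveat)
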