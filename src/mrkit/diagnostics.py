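"""Heterogeneity and pleiotropy diagnostics for an instrument set.

Cochran's Q measures dispersion of the per-SNP Wald ratios about the
fixed-effect IVW estimate; I-squared re-expresses it as the percentage of
variation attributable to heterogeneity rather than chance.  MR-PRESSO is a
simulation-based residual-sum-of-squares framework with three parts: a
global heterogeneity test, a per-SNP outlier test, and a distortion test
comparing the causal estimate before and after outlier removal.  Funnel and
forest plot data are exported as tables for external plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    InsufficientInstrumentsError,
    MREstimate,
    Z975,
    ivw_mre,
)
from .instruments import HarmonisedInstrument

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "cochran_q",
    "funnel_forest_data",
    "mr_presso",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square p-value and the I-squared percentage."""

    q: float
    df: int
    pval: float
    i2: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("q must be non-negative")
        expected = max(0.0, (self.q - self.df) / self.q) * 100.0 if self.q > 0 else 0.0
        if not math.isclose(self.i2, expected, rel_tol=0, abs_tol=1e-9):
            raise ValueError("i2 inconsistent with q and df")


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test outputs.

    Distortion fields are ``None`` when no outlier was detected (or when too
    few SNPs remain after removal to re-estimate).
    """

    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outliers: tuple[str, ...]
    theta_all: MREstimate
    theta_no_outliers: MREstimate | None
    distortion_coef: float | None
    distortion_pval: float | None
    n_sim: int
    seed: int


def cochran_q(instruments: Sequence[HarmonisedInstrument]) -> HeterogeneityResult:
    """Cochran's Q over the Wald ratios with first-order inverse-variance weights.

    Q = sum_j (theta_j - theta_ivw)^2 / v_j where theta_j are the per-SNP
    ratios, v_j their first-order variances and theta_ivw their
    inverse-variance-weighted mean; p from chi-square with J-1 df;
    I2 = max(0, (Q - df)/Q) * 100.
    """
    J = len(instruments)
    if J < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 instruments, got {J}")
    theta = np.array([i.wald_ratio for i in instruments])
    v = np.array([i.wald_se for i in instruments]) ** 2
    theta_ivw = float(np.sum(theta / v) / np.sum(1.0 / v))
    q = float(np.sum((theta - theta_ivw) ** 2 / v))
    df = J - 1
    pval = max(float(stats.chi2.sf(q, df)), 5e-324)
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return HeterogeneityResult(q=q, df=df, pval=pval, i2=i2)


def funnel_forest_data(
    instruments: Sequence[HarmonisedInstrument],
    estimates: Sequence[MREstimate],
) -> pd.DataFrame:
    """Per-SNP ratio rows plus summary-estimator rows for funnel/forest plots.

    SNP rows come first, ordered by ratio ascending (ties by snp_id), then
    one row per summary estimate in the order given.  ``precision`` (1/SE)
    is the funnel-plot vertical axis.
    """
    if not instruments:
        raise ValueError("funnel_forest_data requires at least one instrument")
    rows = []
    for inst in sorted(instruments, key=lambda i: (i.wald_ratio, i.snp_id)):
        r, se = inst.wald_ratio, inst.wald_se
        rows.append(
            {
                "id": inst.snp_id,
                "kind": "snp",
                "estimate": r,
                "se": se,
                "ci_low": r - Z975 * se,
                "ci_high": r + Z975 * se,
                "precision": 1.0 / se,
            }
        )
    for est in estimates:
        rows.append(
            {
                "id": est.method,
                "kind": "summary",
                "estimate": est.theta,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "precision": 1.0 / est.se,
            }
        )
    return pd.DataFrame(rows)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW slopes, one per omitted SNP.

    Vectorised over rows when ``bx``/``by`` are 2-D (n_sim x J); weights are
    shared across rows.
    """
    num = w * bx * by
    den = w * bx * bx
    tot_num = num.sum(axis=-1, keepdims=True)
    tot_den = den.sum(axis=-1, keepdims=True)
    return (tot_num - num) / (tot_den - den)


def mr_presso(
    instruments: Sequence[HarmonisedInstrument],
    n_sim: int = 1000,
    seed: int | None = None,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier and distortion tests.

    Global test: the observed residual sum of squares about the
    leave-one-out IVW slopes is compared with its parametric-simulation null
    (effects redrawn from their normals, outcome centred on the
    leave-one-out prediction).  Outlier test: each SNP's observed squared
    residual against its simulated distribution, Bonferroni-multiplied by J;
    SNPs below ``outlier_alpha`` after adjustment are outliers.  Distortion
    test: the percentage change of the IVW estimate after outlier removal,
    against the change from removing equally many SNPs at random.

    Empirical p-values use the (1 + exceedances)/(n_sim + 1) correction, so
    they lie in [1/(n_sim+1), 1].  Fully reproducible from ``seed``.
    """
    J = len(instruments)
    if J < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO needs >= 4 instruments (leave-one-out fits of >= 3), got {J}"
        )
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if seed is None:
        raise ValueError("a seed is required for the simulations")
    rng = np.random.default_rng(seed)

    bx = np.array([i.beta_x for i in instruments])
    sx = np.array([i.se_x for i in instruments])
    by = np.array([i.beta_y for i in instruments])
    sy = np.array([i.se_y for i in instruments])
    w = sy**-2.0
    ids = [i.snp_id for i in instruments]

    theta_loo = _loo_slopes(bx, by, w)
    r_obs = (by - theta_loo * bx) ** 2
    rss_obs = float(r_obs.sum())

    bx_sim = rng.normal(bx, sx, size=(n_sim, J))
    by_sim = rng.normal(theta_loo * bx, sy, size=(n_sim, J))
    theta_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    r_sim = (by_sim - theta_loo_sim * bx_sim) ** 2
    rss_sim = r_sim.sum(axis=1)

    global_pval = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    raw_p = (1 + (r_sim >= r_obs).sum(axis=0)) / (n_sim + 1)
    outlier_pvals = {s: float(min(p * J, 1.0)) for s, p in zip(ids, raw_p)}
    outliers = tuple(s for s in ids if outlier_pvals[s] < outlier_alpha)

    theta_all = ivw_mre(instruments)
    theta_no: MREstimate | None = None
    distortion_coef: float | None = None
    distortion_pval: float | None = None
    if outliers:
        keep = [i for i in instruments if i.snp_id not in outliers]
        if len(keep) >= 2:
            theta_no = ivw_mre(keep)
            denom = abs(theta_all.theta)
            distortion_coef = 100.0 * (theta_no.theta - theta_all.theta) / denom
            k = len(outliers)
            coefs = np.empty(n_sim)
            idx = np.arange(J)
            for s in range(n_sim):
                drop = rng.choice(idx, size=k, replace=False)
                mask = np.ones(J, dtype=bool)
                mask[drop] = False
                th = _ivw_fixed(bx[mask], by[mask], w[mask])
                coefs[s] = 100.0 * (th - theta_all.theta) / denom
            distortion_pval = (1 + int(np.sum(np.abs(coefs) >= abs(distortion_coef)))) / (
                n_sim + 1
            )
    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outliers=outliers,
        theta_all=theta_all,
        theta_no_outliers=theta_no,
        distortion_coef=distortion_coef,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


def _ivw_fixed(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * bx * by) / np.sum(w * bx * bx))
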