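"""Instrument strength (PVE, F statistic) and analytic power.

For a variance-standardised continuous exposure, a SNP with effect-allele
frequency p and per-allele effect beta (SD units) explains
PVE = 2 p (1-p) beta^2 of the exposure variance; the total over independent
instruments is approximately the sum of the per-SNP values.  Instrument
strength is summarised by the mean F statistic
F = (PVE/(1-PVE)) * (n-k-1)/k, with the Staiger-Stock rule (F > 10) as the
conventional weak-instrument bar.

Power for a continuous exposure on a binary case-control outcome uses the
normal approximation: with N = cases + controls, case fraction v and
b = ln(OR) per SD of exposure, the test statistic is approximately normal
with mean |b| * sqrt(N * PVE * v(1-v)), giving two-sided power
Phi(z - z_{1-a/2}) + Phi(-z - z_{1-a/2}).

Strength and power are defined here for continuous exposures only; for a
binary exposure in a two-sample design there is no accepted analogue and
:class:`BinaryExposureUnsupported` is raised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .sumstats_io import SummaryStatRecord

__all__ = [
    "StrengthReport",
    "PowerRequest",
    "BinaryExposureUnsupported",
    "pve_from_summary",
    "mean_f",
    "assess_strength",
    "power_binary_outcome",
    "power_grid",
]


class BinaryExposureUnsupported(NotImplementedError):
    """Strength/power requested for a binary exposure, which has no analogue here."""


@dataclass(frozen=True)
class StrengthReport:
    """Per-SNP and total PVE with the mean F statistic."""

    pve_per_snp: tuple[float, ...]
    pve_total: float
    mean_f: float
    passes_staiger_stock: bool

    def __post_init__(self) -> None:
        if not math.isclose(self.pve_total, sum(self.pve_per_snp), rel_tol=0, abs_tol=1e-12):
            raise ValueError("pve_total must equal the sum of per-SNP PVEs")
        if self.passes_staiger_stock != (self.mean_f > 10):
            raise ValueError("passes_staiger_stock must equal mean_f > 10")


@dataclass(frozen=True)
class PowerRequest:
    """Inputs for the binary-outcome power approximation."""

    or_alt: float
    pve: float
    n_cases: int
    n_controls: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not (0 < self.pve < 1):
            raise ValueError("pve must lie in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case and control counts must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def pve_from_summary(records: Sequence[SummaryStatRecord]) -> list[float]:
    """Per-SNP proportion of exposure variance explained, 2 p (1-p) beta^2.

    Requires every record to carry an effect-allele frequency and a beta in
    SD units.  Values are clipped to [0, 1) with a warning if a record's
    nominal PVE is that extreme (a sign of a non-standardised beta).
    """
    pves = []
    for rec in records:
        if rec.eaf is None:
            raise ValueError(f"SNP {rec.snp_id} has no effect-allele frequency; PVE undefined")
        pve = 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta**2
        if pve >= 1.0:
            warnings.warn(
                f"SNP {rec.snp_id}: nominal PVE {pve:.3g} clipped below 1; "
                "check that beta is on the SD scale",
                stacklevel=2,
            )
            pve = math.nextafter(1.0, 0.0)
        pves.append(pve)
    return pves


def mean_f(pve_total: float, n: int, k: int) -> float:
    """Mean F statistic from total PVE, GWAS sample size n and k instruments."""
    if not (0 <= pve_total < 1):
        raise ValueError("pve_total must lie in [0, 1)")
    if k < 1:
        raise ValueError("k must be at least 1")
    if n <= k + 1:
        raise ValueError(f"sample size n={n} must exceed k+1={k + 1}")
    return (pve_total / (1.0 - pve_total)) * (n - k - 1) / k


def assess_strength(
    records: Sequence[SummaryStatRecord], n: int, *, trait_type: str = "continuous"
) -> StrengthReport:
    """Full strength report for an instrument set from one exposure GWAS of size n.

    Defined only for continuous exposures; a binary exposure raises
    :class:`BinaryExposureUnsupported`.
    """
    if trait_type == "binary":
        raise BinaryExposureUnsupported(
            "instrument strength is not defined for a binary exposure in a "
            "two-sample design; no PVE/F computed"
        )
    pves = pve_from_summary(records)
    total = sum(pves)
    f = mean_f(total, n, len(records))
    return StrengthReport(
        pve_per_snp=tuple(pves),
        pve_total=total,
        mean_f=f,
        passes_staiger_stock=f > 10,
    )


def power_binary_outcome(req: PowerRequest, *, sided: str = "two") -> float:
    """Analytic power to detect ``or_alt`` per SD of exposure on a binary outcome.

    Two-sided by default; ``sided="one"`` tests in the direction of the
    alternative.  At or_alt = 1 the two-sided power equals alpha exactly.
    """
    N = req.n_cases + req.n_controls
    v = req.n_cases / N
    b = math.log(req.or_alt)
    z = abs(b) * math.sqrt(N * req.pve * v * (1.0 - v))
    if sided == "two":
        c = stats.norm.ppf(1.0 - req.alpha / 2.0)
        return float(stats.norm.cdf(z - c) + stats.norm.cdf(-z - c))
    if sided == "one":
        c = stats.norm.ppf(1.0 - req.alpha)
        return float(stats.norm.cdf(z - c))
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


def power_grid(
    or_values: Sequence[float],
    pve: float,
    n_cases: int,
    n_controls: int,
    alpha: float = 0.05,
    *,
    sided: str = "two",
) -> pd.DataFrame:
    """Power annex: one row per odds ratio in ``or_values``."""
    rows = [
        {
            "or_alt": or_alt,
            "power": power_binary_outcome(
                PowerRequest(or_alt=or_alt, pve=pve, n_cases=n_cases, n_controls=n_controls, alpha=alpha),
                sided=sided,
            ),
        }
        for or_alt in or_values
    ]
    return pd.DataFrame(rows)
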