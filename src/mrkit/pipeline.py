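"""End-to-end two-sample MR analysis: filter, prune, harmonise, estimate,
diagnose, and report.

``run_analysis`` orchestrates the full study design for one exposure and
one outcome and returns a :class:`ReportBundle` holding delimited-text-ready
tables: the stage-by-stage filtering ledger, the estimator table, the
heterogeneity block, the pleiotropy (Egger-intercept) test, the MR-PRESSO
block, the funnel/forest data and, for continuous exposures, the
instrument-strength and power annex.

Estimators are applied by instrument count: a single surviving instrument
yields only its Wald ratio; two allow IVW; three or more additionally allow
MR-Egger, weighted median and weighted mode; four or more allow MR-PRESSO.
For instrument counts above one the reported Wald row is the ratio of the
strongest instrument (largest |beta_x|), kept for reference alongside the
combined estimators.

For binary exposures every estimate is flagged with a caveat: ratio
estimates for a binary exposure on a binary outcome can be inflated in
magnitude when a true effect exists, so the p-value is the primary result
and the OR is reported for completeness only (the estimator table is
ordered p-value-first in that case, and no strength/power annex is
produced).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .diagnostics import PressoResult, cochran_q, funnel_forest_data, mr_presso
from .estimators import (
    BINARY_EXPOSURE,
    SD_EXPOSURE,
    EggerEstimate,
    MREstimate,
    egger,
    ivw_mre,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from .instruments import (
    FilterThresholds,
    StageLog,
    filter_candidates,
    harmonise,
    ld_prune,
)
from .strength_power import assess_strength, power_grid
from .sumstats_io import parse_ld_matrix, parse_summary_stats

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "PipelineError",
    "run_analysis",
    "classify_significance",
]

SIGNIFICANT = "SIGNIFICANT"
SUGGESTIVE = "SUGGESTIVE"
NULL = "NULL"


class PipelineError(RuntimeError):
    """Structured pipeline failure naming the stage that emptied the data."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class AnalysisConfig:
    """Configuration for one exposure-outcome analysis.

    ``alpha_primary`` defaults to the family-wise 0.05 divided by
    ``n_exposures_family`` (two putative risk factors gives the
    conventional 0.025).  ``n_cases``/``n_controls`` describe the outcome
    GWAS and enable the power annex for continuous exposures.
    """

    exposure_path: str | Path
    outcome_path: str | Path
    seed: int
    ld_path: str | Path | None = None
    exposure_trait_type: str = "continuous"
    thresholds: FilterThresholds = dc_field(default_factory=FilterThresholds)
    n_boot: int = 1000
    n_sim: int = 1000
    n_exposures_family: int = 2
    alpha_primary: float | None = None
    power_grid_ors: tuple[float, ...] = (1.05, 1.10, 1.20, 1.50)
    n_cases: int | None = None
    n_controls: int | None = None
    exposure_column_map: dict | None = None
    outcome_column_map: dict | None = None

    def __post_init__(self) -> None:
        if self.exposure_trait_type not in ("continuous", "binary"):
            raise ValueError("exposure_trait_type must be 'continuous' or 'binary'")
        if self.alpha_primary is None:
            self.alpha_primary = 0.05 / self.n_exposures_family
        if not (0 < self.alpha_primary < 1):
            raise ValueError("alpha_primary must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a flat key-value config document; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        thresholds = raw.pop("thresholds", None)
        if thresholds is not None:
            raw["thresholds"] = FilterThresholds(**thresholds)
        if "power_grid_ors" in raw:
            raw["power_grid_ors"] = tuple(raw["power_grid_ors"])
        return cls(**raw)


@dataclass
class ReportBundle:
    """All analysis outputs as tables plus a run log."""

    ledger: pd.DataFrame
    estimates: pd.DataFrame
    heterogeneity: pd.DataFrame | None
    pleiotropy: pd.DataFrame | None
    presso: pd.DataFrame | None
    funnel_forest: pd.DataFrame
    strength: pd.DataFrame | None
    power: pd.DataFrame | None
    classification: str
    primary_method: str
    primary_pval: float
    run_log: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write every table as TSV plus the run log as YAML."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: dict[str, Path] = {}
        for name in ("ledger", "estimates", "heterogeneity", "pleiotropy",
                     "presso", "funnel_forest", "strength", "power"):
            df = getattr(self, name)
            if df is None:
                continue
            path = out_dir / f"{name}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written[name] = path
        log_path = out_dir / "run_log.yaml"
        with open(log_path, "w") as fh:
            yaml.safe_dump(self.run_log, fh, sort_keys=True)
        written["run_log"] = log_path
        return written


def classify_significance(pval: float, alpha_primary: float) -> str:
    """Classify a primary p-value against the corrected threshold.

    p <= alpha_primary is significant; alpha_primary < p < 0.05 is
    suggestive of a causal association; p >= 0.05 is null.
    """
    if not (0 < pval < 1) or not (0 < alpha_primary < 1):
        raise ValueError("pval and alpha_primary must lie in (0, 1)")
    if pval <= alpha_primary:
        return SIGNIFICANT
    if pval < 0.05:
        return SUGGESTIVE
    return NULL


def _estimates_frame(
    estimates: Sequence[MREstimate], binary_exposure: bool
) -> pd.DataFrame:
    rows = [
        {
            "method": e.method,
            "n_snps": e.n_snps,
            "theta": e.theta,
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "pval": e.pval,
            "or_point": e.or_point,
            "or_low": e.or_low,
            "or_high": e.or_high,
            "scale": e.scale,
            "caveat": e.caveat,
        }
        for e in estimates
    ]
    df = pd.DataFrame(rows)
    if binary_exposure:
        # p-value-first layout: ORs demoted to trailing columns ("for completeness")
        order = ["method", "n_snps", "pval", "theta", "se", "ci_low", "ci_high",
                 "scale", "caveat", "or_point", "or_low", "or_high"]
        df = df[order]
    return df


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Run the full two-sample MR study design for one exposure-outcome pair."""
    binary = config.exposure_trait_type == "binary"
    scale = BINARY_EXPOSURE if binary else SD_EXPOSURE
    caveat = binary

    exposure = parse_summary_stats(
        config.exposure_path, config.exposure_column_map, config.exposure_trait_type
    )
    outcome = parse_summary_stats(config.outcome_path, config.outcome_column_map)

    stage_logs: list[StageLog] = []
    candidates = filter_candidates(exposure, config.thresholds, ledger=stage_logs)
    if not candidates:
        raise PipelineError("filter", "no exposure SNP survived the QC filters")

    notes: list[str] = []
    if config.ld_path is not None:
        ld = parse_ld_matrix(config.ld_path)
        candidates = ld_prune(candidates, ld, config.thresholds.ld_r2_max, ledger=stage_logs)
        if not candidates:
            raise PipelineError("ld_prune", "no exposure SNP survived LD pruning")
    else:
        notes.append("ld_prune skipped: no LD matrix supplied")

    instruments = harmonise(candidates, outcome, ledger=stage_logs)
    if not instruments:
        raise PipelineError("harmonise", "no instrument survived harmonisation")
    J = len(instruments)

    # estimator suite by instrument count; Wald row = strongest instrument
    lead = max(instruments, key=lambda i: (abs(i.beta_x), i.snp_id))
    estimates: list[MREstimate] = [wald_ratio(lead, scale=scale, caveat=caveat)]
    egger_est: EggerEstimate | None = None
    if J >= 2:
        estimates.append(ivw_mre(instruments, scale=scale, caveat=caveat))
    if J >= 3:
        egger_est = egger(instruments, scale=scale, caveat=caveat)
        estimates.append(egger_est.slope)
        estimates.append(
            weighted_median(instruments, config.n_boot, config.seed, scale=scale, caveat=caveat)
        )
        estimates.append(
            weighted_mode(
                instruments, 1.0, config.n_boot, config.seed + 1, scale=scale, caveat=caveat
            )
        )
    else:
        notes.append(
            f"only {J} instrument(s): MR-Egger, weighted median and weighted mode not applicable"
        )

    heterogeneity = None
    if J >= 2:
        het = cochran_q(instruments)
        heterogeneity = pd.DataFrame(
            [{"q": het.q, "df": het.df, "pval": het.pval, "i2": het.i2}]
        )

    pleiotropy = None
    if egger_est is not None:
        pleiotropy = pd.DataFrame(
            [
                {
                    "egger_intercept": egger_est.intercept,
                    "se": egger_est.intercept_se,
                    "pval": egger_est.intercept_pval,
                }
            ]
        )

    presso_df = None
    presso: PressoResult | None = None
    if J >= 4:
        presso = mr_presso(instruments, config.n_sim, config.seed + 2)
        presso_df = pd.DataFrame(
            [
                {
                    "rss_obs": presso.rss_obs,
                    "global_pval": presso.global_pval,
                    "n_outliers": len(presso.outliers),
                    "outliers": ";".join(presso.outliers),
                    "theta_no_outliers": (
                        presso.theta_no_outliers.theta if presso.theta_no_outliers else None
                    ),
                    "pval_no_outliers": (
                        presso.theta_no_outliers.pval if presso.theta_no_outliers else None
                    ),
                    "distortion_coef": presso.distortion_coef,
                    "distortion_pval": presso.distortion_pval,
                    "n_sim": presso.n_sim,
                }
            ]
        )
    else:
        notes.append(f"only {J} instrument(s): MR-PRESSO not applicable")

    strength_df = None
    power_df = None
    if not binary:
        n_values = [r.n for r in instruments_records(candidates, instruments) if r.n]
        if n_values and all(r.eaf is not None for r in instruments_records(candidates, instruments)):
            n_x = int(max(n_values))
            strength = assess_strength(instruments_records(candidates, instruments), n_x)
            strength_df = pd.DataFrame(
                [
                    {
                        "pve_total": strength.pve_total,
                        "mean_f": strength.mean_f,
                        "passes_staiger_stock": strength.passes_staiger_stock,
                        "n_exposure": n_x,
                        "k": J,
                    }
                ]
            )
            if config.n_cases and config.n_controls:
                power_df = power_grid(
                    config.power_grid_ors,
                    strength.pve_total,
                    config.n_cases,
                    config.n_controls,
                )
            else:
                notes.append("power annex omitted: outcome case/control counts not configured")
        else:
            notes.append("strength annex omitted: exposure eaf or n missing")
    else:
        notes.append("strength/power not estimated for a binary exposure")

    primary = next((e for e in estimates if e.method == "MRE_IVW"), estimates[0])
    classification = classify_significance(primary.pval, config.alpha_primary)

    ledger_df = pd.DataFrame(
        [
            {
                "stage": s.stage,
                "n_in": s.n_in,
                "n_out": s.n_out,
                "removals": ";".join(f"{k}={v}" for k, v in s.removals.items()),
            }
            for s in stage_logs
        ]
    )

    run_log = {
        "mrkit_version": __version__,
        "seed": config.seed,
        "exposure_trait_type": config.exposure_trait_type,
        "alpha_primary": float(config.alpha_primary),
        "n_boot": config.n_boot,
        "n_sim": config.n_sim,
        "thresholds": asdict(config.thresholds),
        "n_instruments": J,
        "primary_method": primary.method,
        "primary_pval": float(primary.pval),
        "classification": classification,
        "notes": notes,
    }

    return ReportBundle(
        ledger=ledger_df,
        estimates=_estimates_frame(estimates, binary),
        heterogeneity=heterogeneity,
        pleiotropy=pleiotropy,
        presso=presso_df,
        funnel_forest=funnel_forest_data(instruments, estimates),
        strength=strength_df,
        power=power_df,
        classification=classification,
        primary_method=primary.method,
        primary_pval=primary.pval,
        run_log=run_log,
    )


def instruments_records(candidates, instruments):
    """Exposure records of the SNPs that survived harmonisation."""
    surviving = {i.snp_id for i in instruments}
    return [r for r in candidates if r.snp_id in surviving]
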