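"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator draws, per SNP j: a minor-allele frequency, a true per-allele
exposure effect beta_x_j ~ N(0, beta_x_sd^2), and a direct (pleiotropic)
effect alpha_j ~ N(pleiotropy_mean, pleiotropy_sd^2).  The true outcome
effect is

    beta_y_j = theta_true * beta_x_j + sign(beta_x_j) * alpha_j,

i.e. pleiotropy acts on the exposure-increasing allele.  This is the
canonical generative model behind the Egger intercept: after orienting all
exposure effects positive, a non-zero pleiotropy mean shifts the outcome
effects additively.  (An orientation-free additive alpha would cancel under
IVW whenever the beta_x are sign-symmetric, making "directional" pleiotropy
undetectable by construction.)  The InSIDE assumption is violated on demand
by correlating alpha_j with instrument strength |beta_x_j| through a shared
latent normal, with exact target correlation ``inside_violation_corr``.

Standard errors follow the standard GWAS approximation for a standardised
trait, se = (2 p (1-p) n)^(-1/2), with an extra (v(1-v))^(-1/2) factor for
case-control outcomes with case fraction v.  Observed effects are the true
effects plus N(0, se^2) noise; p-values come from the observed z-scores.

Harmonisation is exercised by emitting a configurable fraction of outcome
records with swapped effect/other alleles (beta negated, eaf complemented)
and a configurable fraction of palindromic (A/T, C/G) allele pairs.  A
truth ledger records every latent quantity so tests can cross-check each
pipeline stage.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import LdMatrix, SummaryStatRecord, write_ld_matrix, write_summary_stats

__all__ = [
    "SimulationConfig",
    "simulate_two_sample",
    "identity_ld",
    "block_ld",
    "write_study",
    "bilirubin_like_study",
    "gallstone_like_study",
]

# ordered non-palindromic allele pairs (strand-resolvable)
_NON_PALINDROMIC = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for two-sample summary statistics.

    Defaults describe a well-powered study with strong, independent
    instruments: 50 SNPs, both GWAS of 100,000, effect scale chosen so the
    instrument set explains roughly 18% of exposure variance (per-SNP F in
    the several hundreds), no pleiotropy, a fifth of outcome records
    emitted in the opposite allele orientation and a tenth of SNPs
    palindromic.
    """

    n_snps: int = 50
    theta_true: float = 0.0
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    case_fraction: float | None = None  # None -> continuous outcome
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_x_sd: float = 0.1
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    inside_violation_corr: float = 0.0
    frac_allele_flipped: float = 0.2
    frac_palindromic: float = 0.1
    target_pve: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be at least 1")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("frac_allele_flipped", "frac_palindromic"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (-1 <= self.inside_violation_corr <= 1):
            raise ValueError("inside_violation_corr must lie in [-1, 1]")
        if self.beta_x_sd <= 0:
            raise ValueError("beta_x_sd must be positive")
        if self.pleiotropy_sd < 0:
            raise ValueError("pleiotropy_sd must be non-negative")
        if self.target_pve is not None and not (0 < self.target_pve < 1):
            raise ValueError("target_pve must lie in (0, 1)")


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 5e-324, 1.0)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], pd.DataFrame]:
    """Generate exposure records, outcome records and the truth ledger.

    The truth ledger is a DataFrame with one row per SNP holding every
    latent quantity (true effects, pleiotropy term, SEs, palindromic and
    flipped flags), keyed by ``snp_id``.
    """
    rng = np.random.default_rng(config.seed)
    J = config.n_snps

    maf = rng.uniform(*config.maf_range, size=J)
    u = rng.standard_normal(J)
    beta_x_true = config.beta_x_sd * u
    if config.target_pve is not None:
        current = float(np.sum(2 * maf * (1 - maf) * beta_x_true**2))
        beta_x_true = beta_x_true * math.sqrt(config.target_pve / current)

    # InSIDE-violating correlation: share the standardised |u| latent
    strength = (np.abs(u) - math.sqrt(2 / math.pi)) / math.sqrt(1 - 2 / math.pi)
    rho = config.inside_violation_corr
    z = rng.standard_normal(J)
    alpha = config.pleiotropy_mean + config.pleiotropy_sd * (
        rho * strength + math.sqrt(1 - rho**2) * z
    )
    orient = np.where(beta_x_true >= 0, 1.0, -1.0)
    beta_y_true = config.theta_true * beta_x_true + orient * alpha

    het = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(het * config.n_exposure)
    se_y = 1.0 / np.sqrt(het * config.n_outcome)
    if config.case_fraction is not None:
        v = config.case_fraction
        se_y = se_y / math.sqrt(v * (1.0 - v))

    beta_x_obs = beta_x_true + rng.normal(0.0, se_x)
    beta_y_obs = beta_y_true + rng.normal(0.0, se_y)

    n_pal = round(config.frac_palindromic * J)
    pal_idx = set(rng.choice(J, size=n_pal, replace=False).tolist()) if n_pal else set()
    n_flip = round(config.frac_allele_flipped * J)
    flip_idx = set(rng.choice(J, size=n_flip, replace=False).tolist()) if n_flip else set()
    pair_choice = rng.integers(0, len(_NON_PALINDROMIC), size=J)
    pal_choice = rng.integers(0, len(_PALINDROMIC), size=J)

    info_x = rng.uniform(0.9, 1.0, size=J)
    info_y = rng.uniform(0.9, 1.0, size=J)

    exposure: list[SummaryStatRecord] = []
    outcome: list[SummaryStatRecord] = []
    truth_rows = []
    px = _pvals(beta_x_obs, se_x)
    py = _pvals(beta_y_obs, se_y)
    for j in range(J):
        snp = f"rs{j + 1:06d}"
        ea, oa = _PALINDROMIC[pal_choice[j]] if j in pal_idx else _NON_PALINDROMIC[pair_choice[j]]
        exposure.append(
            SummaryStatRecord(
                snp_id=snp,
                chrom=str(j % 22 + 1),
                pos=(j + 1) * 1_000_000,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(maf[j]),
                beta=float(beta_x_obs[j]),
                se=float(se_x[j]),
                pval=float(px[j]),
                info=float(info_x[j]),
                n=config.n_exposure,
            )
        )
        flipped = j in flip_idx
        outcome.append(
            SummaryStatRecord(
                snp_id=snp,
                chrom=str(j % 22 + 1),
                pos=(j + 1) * 1_000_000,
                effect_allele=oa if flipped else ea,
                other_allele=ea if flipped else oa,
                eaf=float(1.0 - maf[j]) if flipped else float(maf[j]),
                beta=float(-beta_y_obs[j]) if flipped else float(beta_y_obs[j]),
                se=float(se_y[j]),
                pval=float(py[j]),
                info=float(info_y[j]),
                n=config.n_outcome,
            )
        )
        truth_rows.append(
            {
                "snp_id": snp,
                "maf": float(maf[j]),
                "beta_x_true": float(beta_x_true[j]),
                "beta_y_true": float(beta_y_true[j]),
                "alpha": float(alpha[j]),
                "se_x": float(se_x[j]),
                "se_y": float(se_y[j]),
                "beta_x_obs": float(beta_x_obs[j]),
                "beta_y_obs": float(beta_y_obs[j]),
                "palindromic": j in pal_idx,
                "flipped": flipped,
                "theta_true": config.theta_true,
            }
        )
    return exposure, outcome, pd.DataFrame(truth_rows)


def identity_ld(snp_ids: list[str]) -> LdMatrix:
    """LD matrix for mutually independent instruments (identity r-squared)."""
    return LdMatrix(snp_ids=tuple(snp_ids), r2=np.eye(len(snp_ids)))


def block_ld(snp_ids: list[str], block_size: int, r2_within: float = 0.8) -> LdMatrix:
    """Block-structured LD: consecutive blocks share ``r2_within``, blocks independent."""
    n = len(snp_ids)
    m = np.eye(n)
    for start in range(0, n, block_size):
        end = min(start + block_size, n)
        m[start:end, start:end] = r2_within
    np.fill_diagonal(m, 1.0)
    return LdMatrix(snp_ids=tuple(snp_ids), r2=m)


def write_study(
    out_dir: str | Path,
    exposure: list[SummaryStatRecord],
    outcome: list[SummaryStatRecord],
    truth: pd.DataFrame | None = None,
    ld: LdMatrix | None = None,
) -> dict[str, Path]:
    """Write a simulated study as the canonical delimited-text files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": out_dir / "exposure.tsv",
        "outcome": out_dir / "outcome.tsv",
    }
    write_summary_stats(exposure, paths["exposure"])
    write_summary_stats(outcome, paths["outcome"])
    if truth is not None:
        paths["truth"] = out_dir / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
    if ld is not None:
        paths["ld"] = out_dir / "ld.tsv"
        write_ld_matrix(ld, paths["ld"])
    return paths


def _record(snp, chrom, pos, ea, oa, eaf, beta, n, *, se=None, info=0.98, cf=None):
    het = 2.0 * eaf * (1.0 - eaf)
    if se is None:
        se = 1.0 / math.sqrt(het * n) if cf is None else 1.0 / math.sqrt(het * n * cf * (1 - cf))
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta) / se), 5e-324, 1.0))
    return SummaryStatRecord(
        snp_id=snp, chrom=chrom, pos=pos, effect_allele=ea, other_allele=oa,
        eaf=eaf, beta=beta, se=se, pval=p, info=info, n=n,
    )


def bilirubin_like_study() -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], LdMatrix]:
    """Synthetic deterministic study with two strong instruments for a
    continuous, SD-standardised exposure and a null case-control outcome.

    Emulates the configuration of a bilirubin-style analysis: two
    independent SNPs jointly explaining 18.0% of exposure variance in a
    GWAS of 9464, tested against a null outcome GWAS of 26,397 cases and
    41,481 controls.  The second outcome record is emitted with swapped
    alleles to exercise harmonisation.  Entirely synthetic — no real
    summary statistics are reproduced.
    """
    n_x, n_cases, n_controls = 9464, 26_397, 41_481
    n_y = n_cases + n_controls
    cf = n_cases / n_y
    # second SNP contributes 2*0.3*0.7*0.27^2; the first is solved so the
    # instrument set explains exactly 18% of exposure variance
    beta2 = 0.27
    beta1 = math.sqrt((0.18 - 2 * 0.3 * 0.7 * beta2**2) / (2 * 0.45 * 0.55))
    exposure = [
        _record("rs000101", "2", 234_000_000, "A", "G", 0.45, beta1, n_x),
        _record("rs000202", "12", 21_000_000, "C", "T", 0.30, beta2, n_x),
    ]
    outcome = [
        _record("rs000101", "2", 234_000_000, "A", "G", 0.45, 0.002, n_y, cf=cf),
        # swapped orientation: harmonised outcome effect is -0.003
        _record("rs000202", "12", 21_000_000, "T", "C", 0.70, 0.003, n_y, cf=cf),
    ]
    return exposure, outcome, identity_ld([r.snp_id for r in exposure])


def gallstone_like_study() -> tuple[list[SummaryStatRecord], list[SummaryStatRecord], LdMatrix]:
    """Synthetic deterministic study with 26 instruments for a binary
    exposure and a heterogeneous case-control outcome.

    Emulates a gallstone-style analysis: 26 independent genome-wide
    significant SNPs from a large case-control exposure GWAS (27,174 cases
    / 736,838 controls; effects in log-odds units), tested against an
    outcome GWAS of 26,397 cases / 41,481 controls whose effects carry
    deliberate heterogeneity, including three planted outliers displaced by
    ten outcome-SEs.  Orientation flips and strand flips are planted at
    fixed positions to exercise harmonisation.  Entirely synthetic.
    """
    n_x_cases, n_x_controls = 27_174, 736_838
    n_x = n_x_cases + n_x_controls
    cf_x = n_x_cases / n_x
    n_cases, n_controls = 26_397, 41_481
    n_y = n_cases + n_controls
    cf_y = n_cases / n_y

    complement = {"A": "T", "T": "A", "C": "G", "G": "C"}
    pairs = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"), ("T", "C"), ("G", "A")]
    wiggle = [0.004, -0.006, 0.009, -0.003, 0.007, -0.008, 0.005]
    outlier_pos = {5, 12, 19}

    exposure, outcome = [], []
    for j in range(26):
        snp = f"rs{j + 1:05d}0"
        chrom, pos = str(j % 22 + 1), (j + 3) * 2_500_000
        eaf = 0.10 + 0.015 * j
        beta_x = (0.10 + 0.02 * j) * (1 if j % 2 == 0 else -1)
        ea, oa = pairs[j % len(pairs)]
        exposure.append(_record(snp, chrom, pos, ea, oa, eaf, beta_x, n_x, cf=cf_x))

        het = 2.0 * eaf * (1.0 - eaf)
        se_y = 1.0 / math.sqrt(het * n_y * cf_y * (1 - cf_y))
        beta_y = 0.2 * beta_x + wiggle[j % len(wiggle)]
        if j in outlier_pos:
            beta_y += 10.0 * se_y
        ea_y, oa_y, eaf_y = ea, oa, eaf
        if j % 5 == 1:  # orientation flip
            ea_y, oa_y, eaf_y, beta_y = oa, ea, 1.0 - eaf, -beta_y
        if j % 7 == 3:  # strand flip (non-palindromic, so resolvable)
            ea_y, oa_y = complement[ea_y], complement[oa_y]
        outcome.append(
            _record(snp, chrom, pos, ea_y, oa_y, eaf_y, beta_y, n_y, se=se_y)
        )
    return exposure, outcome, identity_ld([r.snp_id for r in exposure])
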