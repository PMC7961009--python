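"""Instrument construction: QC filtering, greedy LD pruning, harmonisation.

Candidate instruments are genome-wide significant SNPs (P < 5e-8) with minor
allele frequency above 0.01 and imputation info score of at least 0.8.
Correlated candidates are pruned greedily at r-squared >= 0.01, keeping the
SNP with the strongest effect size.  Exposure and outcome records are then
harmonised to a common effect allele, with palindromic (A/T, C/G) SNPs
removed outright because their strand cannot be resolved from the alleles.

Each step can append :class:`StageLog` entries to a caller-supplied ledger,
producing a flowchart-style accounting of SNPs in, SNPs out, and removal
reasons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .sumstats_io import LdMatrix, SummaryStatRecord

__all__ = [
    "FilterThresholds",
    "HarmonisedInstrument",
    "StageLog",
    "InstrumentError",
    "filter_candidates",
    "ld_prune",
    "harmonise",
]

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele pairs whose strand cannot be inferred from the alleles alone
PALINDROMIC_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})


class InstrumentError(ValueError):
    """Raised for invalid instrument-construction inputs."""


@dataclass(frozen=True)
class FilterThresholds:
    """QC thresholds for candidate instruments.

    Defaults are the conventional genome-wide pipeline values: significance
    5e-8, MAF floor 0.01, info floor 0.8 and LD pruning at r-squared 0.01.
    ``allow_missing_info`` controls whether records lacking an info score may
    pass the imputation filter (off by default — conservative).
    """

    pval_max: float = 5e-8
    maf_min: float = 0.01
    info_min: float = 0.8
    ld_r2_max: float = 0.01
    allow_missing_info: bool = False

    def __post_init__(self) -> None:
        for name in ("pval_max", "maf_min", "info_min", "ld_r2_max"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise InstrumentError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class HarmonisedInstrument:
    """A SNP with exposure and outcome effects aligned to one effect allele.

    ``wald_ratio`` is the per-SNP causal estimate beta_y / beta_x and
    ``wald_se`` its first-order (delta-method) standard error se_y/|beta_x|.
    """

    snp_id: str
    beta_x: float
    se_x: float
    beta_y: float
    se_y: float
    eaf: float | None
    wald_ratio: float
    wald_se: float

    def __post_init__(self) -> None:
        if self.beta_x == 0:
            raise InstrumentError(f"{self.snp_id}: beta_x must be non-zero")
        if self.se_x <= 0 or self.se_y <= 0:
            raise InstrumentError(f"{self.snp_id}: standard errors must be positive")
        if not math.isclose(self.wald_ratio, self.beta_y / self.beta_x, rel_tol=0, abs_tol=1e-12):
            raise InstrumentError(f"{self.snp_id}: wald_ratio inconsistent with beta_y/beta_x")

    @classmethod
    def from_effects(
        cls,
        snp_id: str,
        beta_x: float,
        se_x: float,
        beta_y: float,
        se_y: float,
        eaf: float | None = None,
    ) -> "HarmonisedInstrument":
        return cls(
            snp_id=snp_id,
            beta_x=beta_x,
            se_x=se_x,
            beta_y=beta_y,
            se_y=se_y,
            eaf=eaf,
            wald_ratio=beta_y / beta_x,
            wald_se=se_y / abs(beta_x),
        )


@dataclass
class StageLog:
    """One filtering-ledger row: stage name, counts, removal reasons."""

    stage: str
    n_in: int
    n_out: int
    removals: dict[str, int] = field(default_factory=dict)


def filter_candidates(
    records: list[SummaryStatRecord],
    thresholds: FilterThresholds = FilterThresholds(),
    *,
    ledger: list[StageLog] | None = None,
) -> list[SummaryStatRecord]:
    """Apply significance, MAF and imputation-quality filters.

    A record is retained iff ``pval < pval_max``, ``min(eaf, 1-eaf) >
    maf_min`` and ``info >= info_min``.  Records with missing eaf fail the
    MAF filter; records with missing info fail the info filter unless
    ``thresholds.allow_missing_info``.  Exclusions are counted by the first
    criterion failed, in the order significance, MAF, info.
    """
    if not records:
        logger.warning("filter_candidates: empty input")
        if ledger is not None:
            ledger.append(StageLog("filter", 0, 0))
        return []
    kept: list[SummaryStatRecord] = []
    removals = {"significance": 0, "maf": 0, "info": 0}
    for rec in records:
        if not rec.pval < thresholds.pval_max:
            removals["significance"] += 1
        elif rec.maf is None or not rec.maf > thresholds.maf_min:
            removals["maf"] += 1
        elif rec.info is None:
            if thresholds.allow_missing_info:
                kept.append(rec)
            else:
                removals["info"] += 1
        elif rec.info >= thresholds.info_min:
            kept.append(rec)
        else:
            removals["info"] += 1
    if ledger is not None:
        ledger.append(
            StageLog("filter", len(records), len(kept), {k: v for k, v in removals.items() if v})
        )
    return kept


def ld_prune(
    records: list[SummaryStatRecord],
    ld: LdMatrix,
    r2_max: float = 0.01,
    *,
    ledger: list[StageLog] | None = None,
) -> list[SummaryStatRecord]:
    """Greedy LD pruning keeping the strongest effects.

    Records are visited in order of decreasing ``|beta|`` (ties broken by
    ascending snp_id for determinism); a record is retained iff its
    r-squared with every already-retained record is below ``r2_max``.  The
    retained set is therefore pairwise r2 < r2_max, and the SNP with the
    largest effect always survives.
    """
    if not (0 < r2_max <= 1):
        raise InstrumentError(f"r2_max must lie in (0, 1], got {r2_max}")
    for rec in records:
        if rec.snp_id not in ld:
            raise InstrumentError(f"SNP {rec.snp_id} absent from the LD matrix")
    ranked = sorted(records, key=lambda r: (-abs(r.beta), r.snp_id))
    kept: list[SummaryStatRecord] = []
    for rec in ranked:
        if all(ld.r2_between(rec.snp_id, k.snp_id) < r2_max for k in kept):
            kept.append(rec)
    # restore the input order among survivors
    kept_ids = {r.snp_id for r in kept}
    out = [r for r in records if r.snp_id in kept_ids]
    if ledger is not None:
        ledger.append(StageLog("ld_prune", len(records), len(out), {"correlated": len(records) - len(out)}))
    return out


def _is_palindromic(a: str, b: str) -> bool:
    return (a, b) in PALINDROMIC_PAIRS


def harmonise(
    exposure: list[SummaryStatRecord],
    outcome: list[SummaryStatRecord],
    *,
    ledger: list[StageLog] | None = None,
) -> list[HarmonisedInstrument]:
    """Align outcome effects to the exposure effect allele per SNP.

    The exposure records define the reference orientation.  For each SNP in
    both datasets:

    * identical allele pair, same orientation — outcome effect copied;
    * effect/other alleles swapped — outcome beta negated, eaf complemented;
    * alleles reconcilable only by strand complement (A<->T, C<->G) — the
      outcome alleles are complemented, then the two rules above apply;
    * palindromic allele pairs (A/T or C/G) — removed: strand unresolvable;
    * anything else — removed as incompatible.

    SNPs missing from the outcome dataset and SNPs with a null exposure
    effect are removed with a logged reason.  Each retained SNP carries its
    Wald ratio and first-order SE.
    """
    out_by_id = {r.snp_id: r for r in outcome}
    instruments: list[HarmonisedInstrument] = []
    removals = {
        "missing_in_outcome": 0,
        "palindromic": 0,
        "incompatible_alleles": 0,
        "null_exposure_effect": 0,
    }
    for ex in exposure:
        oc = out_by_id.get(ex.snp_id)
        if oc is None:
            removals["missing_in_outcome"] += 1
            continue
        if _is_palindromic(ex.effect_allele, ex.other_allele) or _is_palindromic(
            oc.effect_allele, oc.other_allele
        ):
            removals["palindromic"] += 1
            continue
        pair = (oc.effect_allele, oc.other_allele)
        flipped_pair = (COMPLEMENT[oc.effect_allele], COMPLEMENT[oc.other_allele])
        ref = (ex.effect_allele, ex.other_allele)
        swap = (ex.other_allele, ex.effect_allele)
        if pair == ref or flipped_pair == ref:
            beta_y, eaf_y = oc.beta, oc.eaf
        elif pair == swap or flipped_pair == swap:
            beta_y = -oc.beta
            eaf_y = None if oc.eaf is None else 1.0 - oc.eaf
        else:
            removals["incompatible_alleles"] += 1
            continue
        del eaf_y  # outcome frequency only informs the alignment; exposure eaf is reported
        if ex.beta == 0:
            removals["null_exposure_effect"] += 1
            continue
        instruments.append(
            HarmonisedInstrument.from_effects(
                snp_id=ex.snp_id,
                beta_x=ex.beta,
                se_x=ex.se,
                beta_y=beta_y,
                se_y=oc.se,
                eaf=ex.eaf,
            )
        )
    for reason, count in removals.items():
        if count:
            logger.info("harmonise: removed %d SNP(s): %s", count, reason)
    if ledger is not None:
        ledger.append(
            StageLog(
                "harmonise",
                len(exposure),
                len(instruments),
                {k: v for k, v in removals.items() if v},
            )
        )
    return instruments
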