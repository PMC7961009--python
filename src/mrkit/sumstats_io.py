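"""Reading, validating and writing GWAS summary statistics and LD matrices.

Summary-statistic tables are delimited text with a header row; the canonical
column set is ``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta,
se, pval, info, n`` but any source naming can be remapped via a
``column_map``.  Effects are per-allele, in SD units of the trait for
continuous traits and log-odds for binary traits.  LD matrices are square
r-squared tables keyed by variant identifier on both axes.

Only biallelic SNPs are accepted: indels and multi-allelic records are
rejected row-by-row at parse time with a diagnostic, not an exception.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "LdMatrix",
    "ParseReport",
    "SumStatsError",
    "parse_summary_stats",
    "parse_summary_stats_report",
    "write_summary_stats",
    "parse_ld_matrix",
    "write_ld_matrix",
    "CANONICAL_COLUMNS",
]

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "info",
    "n",
)

#: fields a row must parse for the record to be accepted
MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

#: strings treated as missing for the optional fields (eaf, info, n, chrom, pos)
NA_STRINGS = frozenset({"", "NA", "NaN", "nan", "na", "."})


class SumStatsError(ValueError):
    """Raised for malformed summary-statistic or LD inputs."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` (SD units for
    continuous traits, log-odds for binary traits); ``eaf`` is the
    effect-allele frequency.  ``eaf``, ``info`` and ``n`` may be ``None``.
    """

    snp_id: str
    chrom: str | None
    pos: int | None
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    info: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise SumStatsError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T "
                f"(got {self.effect_allele!r}/{self.other_allele!r})"
            )
        if self.effect_allele == self.other_allele:
            raise SumStatsError(f"{self.snp_id}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise SumStatsError(f"{self.snp_id}: beta must be finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise SumStatsError(f"{self.snp_id}: se must be positive and finite")
        if not (0 < self.pval <= 1):
            raise SumStatsError(f"{self.snp_id}: pval must lie in (0, 1]")
        for name in ("eaf", "info"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise SumStatsError(f"{self.snp_id}: {name} must lie in [0, 1]")
        if self.pos is not None and self.pos < 0:
            raise SumStatsError(f"{self.snp_id}: pos must be non-negative")
        if self.n is not None and self.n <= 0:
            raise SumStatsError(f"{self.snp_id}: n must be positive")

    @property
    def maf(self) -> float | None:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``; ``None`` if eaf missing."""
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def with_(self, **changes) -> "SummaryStatRecord":
        return replace(self, **changes)


@dataclass(frozen=True)
class LdMatrix:
    """Square symmetric r-squared matrix keyed by variant identifier."""

    snp_ids: tuple[str, ...]
    r2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if r2.shape != (n, n):
            raise SumStatsError(f"LD matrix shape {r2.shape} does not match {n} identifiers")
        if len(set(self.snp_ids)) != n:
            raise SumStatsError("duplicate identifiers in LD matrix")
        if not np.allclose(r2, r2.T, atol=1e-8, rtol=0):
            raise SumStatsError("LD matrix is asymmetric beyond 1e-8")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-8, rtol=0):
            raise SumStatsError("LD matrix diagonal differs from 1 beyond 1e-8")
        if r2.min() < 0 or r2.max() > 1 + 1e-8:
            raise SumStatsError("LD r2 values must lie in [0, 1]")
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.snp_ids)})

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])


@dataclass
class ParseReport:
    """Accepted records plus row-level diagnostics for rejected rows."""

    records: list[SummaryStatRecord]
    rejected: list[tuple[int, str]]  # (1-based data-row number, reason)

    @property
    def n_total(self) -> int:
        return len(self.records) + len(self.rejected)


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if not header.strip():
        raise SumStatsError(f"{path}: empty file")
    return "\t" if "\t" in header else ","


def _get(row: Mapping[str, str], col: str | None) -> str | None:
    if col is None:
        return None
    v = row.get(col)
    if v is None:
        return None
    v = str(v).strip()
    return None if v in NA_STRINGS else v


def parse_summary_stats_report(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
) -> ParseReport:
    """Parse a summary-statistics table, keeping row-level diagnostics.

    ``column_map`` maps canonical field names to the source file's column
    names; unmapped canonical names are looked up verbatim.  Rows whose
    mandatory fields (snp_id, alleles, beta, se, pval) fail to parse are
    rejected with a reason rather than aborting the parse; missing optional
    fields become ``None``.
    """
    if trait_type not in ("continuous", "binary"):
        raise SumStatsError(f"trait_type must be 'continuous' or 'binary', got {trait_type!r}")
    path = Path(path)
    if not path.exists():
        raise SumStatsError(f"no such file: {path}")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.empty:
        raise SumStatsError(f"{path}: no data rows")

    cmap = dict(column_map or {})
    resolved: dict[str, str | None] = {}
    for canon in CANONICAL_COLUMNS:
        source = cmap.get(canon, canon)
        if source in df.columns:
            resolved[canon] = source
        elif canon in MANDATORY_FIELDS:
            raise SumStatsError(f"{path}: mandatory column {canon!r} (source {source!r}) missing from header")
        else:
            resolved[canon] = None

    records: list[SummaryStatRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            pos_raw = _get(row, resolved["pos"])
            n_raw = _get(row, resolved["n"])
            rec = SummaryStatRecord(
                snp_id=_require(row, resolved, "snp_id"),
                chrom=_get(row, resolved["chrom"]),
                pos=int(float(pos_raw)) if pos_raw is not None else None,
                effect_allele=_require(row, resolved, "effect_allele"),
                other_allele=_require(row, resolved, "other_allele"),
                eaf=_maybe_float(row, resolved, "eaf"),
                beta=float(_require(row, resolved, "beta")),
                se=float(_require(row, resolved, "se")),
                pval=float(_require(row, resolved, "pval")),
                info=_maybe_float(row, resolved, "info"),
                n=int(float(n_raw)) if n_raw is not None else None,
            )
        except (SumStatsError, ValueError) as exc:
            rejected.append((i, str(exc)))
            continue
        records.append(rec)

    ids = [r.snp_id for r in records]
    dupes = sorted({s for s in ids if ids.count(s) > 1})
    if dupes:
        raise SumStatsError(f"{path}: duplicate snp_id values: {', '.join(dupes)}")
    for rownum, reason in rejected:
        logger.warning("%s: rejected data row %d: %s", path, rownum, reason)
    return ParseReport(records=records, rejected=rejected)


def _require(row, resolved, canon: str) -> str:
    v = _get(row, resolved[canon])
    if v is None:
        raise SumStatsError(f"missing mandatory field {canon!r}")
    return v


def _maybe_float(row, resolved, canon: str) -> float | None:
    v = _get(row, resolved[canon])
    return float(v) if v is not None else None


def parse_summary_stats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
) -> list[SummaryStatRecord]:
    """Parse a summary-statistics table; see :func:`parse_summary_stats_report`."""
    return parse_summary_stats_report(path, column_map, trait_type).records


def _fmt(v) -> str:
    if v is None:
        return "NA"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_summary_stats(
    records: Iterable[SummaryStatRecord], path: str | Path, delimiter: str = "\t"
) -> None:
    """Write records in the canonical column layout.

    Floats are written with their shortest round-tripping representation, so
    a write/parse cycle reproduces every field bit-exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(delimiter.join(CANONICAL_COLUMNS) + "\n")
        for r in records:
            fh.write(
                delimiter.join(
                    _fmt(getattr(r, c)) for c in CANONICAL_COLUMNS
                )
                + "\n"
            )


def parse_ld_matrix(path: str | Path) -> LdMatrix:
    """Parse a square r-squared table; first row and column are identifiers."""
    path = Path(path)
    if not path.exists():
        raise SumStatsError(f"no such file: {path}")
    sep = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise SumStatsError(f"{path}: LD matrix is not square ({df.shape[0]}x{df.shape[1]})")
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise SumStatsError(f"{path}: LD matrix row and column identifiers differ")
    return LdMatrix(snp_ids=tuple(str(s) for s in df.index), r2=df.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | Path, delimiter: str = "\t") -> None:
    pd.DataFrame(ld.r2, index=list(ld.snp_ids), columns=list(ld.snp_ids)).to_csv(
        path, sep=delimiter
    )
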