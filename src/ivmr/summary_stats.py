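"""Typed GWAS summary-statistic records and tab-separated file I/O.

The atoms of a two-sample Mendelian randomization analysis are per-SNP
association records: for each variant, an additive per-allele effect
(beta), its standard error, the effect allele the beta is expressed on,
and optionally the effect-allele frequency (EAF), p-value and sample
size.  Exposure-side records are grouped into an :class:`InstrumentSet`
(one per exposure trait); outcome-side records into an
:class:`OutcomePanel` (one per outcome trait).

Files are plain TSV with a header row.  Because consortium exports
disagree on header vocabulary, column names are resolved through a
*dialect* mapping (logical field -> column name); the default dialect
matches the headers used by this package's own writers and bundled
tables.
"""

from __future__ import annotations

import dataclasses
import math
import re
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "GwasRecord",
    "InstrumentSet",
    "OutcomePanel",
    "ReadResult",
    "RowDiagnostic",
    "SummaryStatsError",
    "FormatError",
    "DEFAULT_DIALECT",
    "parse_number",
    "read_summary_table",
    "write_summary_table",
    "write_results_table",
    "read_results_table",
]

VALID_BASES = frozenset("ACGT")
_RSID_RE = re.compile(r"^rs[0-9]+$")

#: Printed-style scientific notation, e.g. "3.56 × 10^−8" or "2.2 x 10^- 4".
_SCI_RE = re.compile(
    r"^\s*([+-]?\d+(?:\.\d+)?)\s*[×xX✕]\s*10\s*\^?\s*([+-]?\s*\d+)\s*$"
)


class SummaryStatsError(ValueError):
    """Base error for summary-statistic parsing and validation."""


class FormatError(SummaryStatsError):
    """A file-level problem: missing mandatory column, duplicate ids."""


def parse_number(text: str | float) -> float:
    """Parse a numeric cell, accepting printed scientific notation.

    Handles ordinary floats and e-notation, plus the typeset forms that
    appear in published tables: a multiplication sign with a caret
    exponent ("4.40 × 10^−11"), Unicode minus signs, and stray spaces
    inside the exponent.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = str(text).strip().replace("−", "-").replace("–", "-")
    m = _SCI_RE.match(s)
    if m:
        mantissa, exponent = m.group(1), m.group(2).replace(" ", "")
        return float(f"{mantissa}e{exponent}")
    return float(s)


@dataclasses.dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with one trait.

    ``beta`` is the additive per-allele effect of ``effect_allele`` on
    ``trait``; ``se`` its standard error.  ``other_allele`` may be
    unknown (some published instrument tables print only the effect
    allele), in which case harmonization degrades gracefully.  ``eaf``
    is the effect-allele frequency and is only required to orient
    palindromic variants.
    """

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    trait: str = ""
    other_allele: str | None = None
    chrom: str | None = None
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None
    gene: str | None = None

    def __post_init__(self) -> None:
        if not _RSID_RE.match(self.snp_id):
            raise SummaryStatsError(f"snp_id {self.snp_id!r} is not an rsID")
        if self.effect_allele not in VALID_BASES:
            raise SummaryStatsError(
                f"{self.snp_id}: effect_allele {self.effect_allele!r} is not a single base"
            )
        if self.other_allele is not None:
            if self.other_allele not in VALID_BASES:
                raise SummaryStatsError(
                    f"{self.snp_id}: other_allele {self.other_allele!r} is not a single base"
                )
            if self.other_allele == self.effect_allele:
                raise SummaryStatsError(f"{self.snp_id}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise SummaryStatsError(f"{self.snp_id}: beta is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise SummaryStatsError(f"{self.snp_id}: se must be finite and > 0")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise SummaryStatsError(f"{self.snp_id}: eaf {self.eaf} outside [0, 1]")
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise SummaryStatsError(f"{self.snp_id}: pvalue {self.pvalue} outside (0, 1]")


@dataclasses.dataclass(frozen=True)
class InstrumentSet:
    """The instruments (genetic variants) proposed for one exposure."""

    exposure_name: str
    records: tuple[GwasRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise SummaryStatsError(f"instrument set {self.exposure_name!r} is empty")
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SummaryStatsError(
                f"instrument set {self.exposure_name!r} has duplicate snp_ids"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GwasRecord]:
        return iter(self.records)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(r.snp_id for r in self.records)


@dataclasses.dataclass(frozen=True)
class OutcomePanel:
    """Per-SNP associations with one outcome, keyed by rsID."""

    outcome_name: str
    records: tuple[GwasRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise SummaryStatsError(f"outcome panel {self.outcome_name!r} has duplicate snp_ids")
        object.__setattr__(self, "_index", {r.snp_id: r for r in self.records})

    def __len__(self) -> int:
        return len(self.records)

    def get(self, snp_id: str) -> GwasRecord | None:
        return self._index.get(snp_id)  # type: ignore[attr-defined]

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index  # type: ignore[attr-defined]


@dataclasses.dataclass(frozen=True)
class RowDiagnostic:
    """Why one input row was rejected (1-based data line number)."""

    line: int
    snp_id: str
    message: str


@dataclasses.dataclass(frozen=True)
class ReadResult(Sequence):
    """Accepted records plus row-level diagnostics for rejected rows."""

    records: tuple[GwasRecord, ...]
    diagnostics: tuple[RowDiagnostic, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):  # type: ignore[override]
        return self.records[i]


#: Logical field -> column header used when no dialect is supplied.
DEFAULT_DIALECT: Mapping[str, str] = {
    "snp_id": "snp_id",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "beta": "beta",
    "se": "se",
    "pvalue": "pvalue",
    "eaf": "eaf",
    "chrom": "chrom",
    "trait": "trait",
    "n": "n",
    "gene": "gene",
}

_MANDATORY = ("snp_id", "effect_allele", "beta", "se")
_OPTIONAL_FLOAT = ("eaf", "pvalue")


def read_summary_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    trait: str | None = None,
) -> ReadResult:
    """Read per-SNP summary statistics from a TSV file.

    Rows violating record invariants (non-positive SE, frequency outside
    [0, 1], malformed rsID, unparseable numbers, ...) are rejected
    individually and reported in :attr:`ReadResult.diagnostics`; valid
    rows are returned in file order.  A missing mandatory column or a
    duplicate (trait, snp_id, effect_allele) triple raises
    :class:`FormatError` — those indicate a malformed file, not a bad
    row.

    Parameters
    ----------
    path:
        TSV file with a header row.
    dialect:
        Mapping from logical field names (see ``DEFAULT_DIALECT``) to
        the column headers used in this file.  Unmapped optional fields
        fall back to their default header and are ignored if absent.
    trait:
        Trait label to stamp on every record when the file has no trait
        column.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field in _MANDATORY:
        if dialect[field] not in frame.columns:
            raise FormatError(
                f"{path.name}: mandatory column {dialect[field]!r} (field {field!r}) missing"
            )

    records: list[GwasRecord] = []
    diagnostics: list[RowDiagnostic] = []
    seen: set[tuple[str, str, str]] = set()

    def cell(row, field: str) -> str | None:
        col = dialect[field]
        if col not in frame.columns:
            return None
        value = str(row[col]).strip()
        return value or None

    for line, (_, row) in enumerate(frame.iterrows(), start=1):
        snp_id = cell(row, "snp_id") or ""
        try:
            kwargs: dict = {
                "snp_id": snp_id,
                "effect_allele": (cell(row, "effect_allele") or "").upper(),
                "beta": parse_number(cell(row, "beta") or "nan"),
                "se": parse_number(cell(row, "se") or "nan"),
            }
            other = cell(row, "other_allele")
            if other is not None:
                kwargs["other_allele"] = other.upper()
            for field in _OPTIONAL_FLOAT:
                raw = cell(row, field)
                if raw is not None:
                    kwargs[field] = parse_number(raw)
            raw_n = cell(row, "n")
            if raw_n is not None:
                kwargs["n"] = int(float(raw_n))
            for field in ("chrom", "gene"):
                raw = cell(row, field)
                if raw is not None:
                    kwargs[field] = raw
            kwargs["trait"] = cell(row, "trait") or trait or ""
            record = GwasRecord(**kwargs)
        except (SummaryStatsError, ValueError) as exc:
            diagnostics.append(RowDiagnostic(line, snp_id, str(exc)))
            continue
        key = (record.trait, record.snp_id, record.effect_allele)
        if key in seen:
            raise FormatError(
                f"{path.name}: duplicate snp_id {record.snp_id!r} for trait "
                f"{record.trait!r} (effect allele {record.effect_allele})"
            )
        seen.add(key)
        records.append(record)
    return ReadResult(tuple(records), tuple(diagnostics))


def write_summary_table(records: Sequence[GwasRecord], path: str | Path) -> None:
    """Write records as TSV in the default dialect, full float precision."""
    rows = []
    for r in records:
        rows.append(
            {
                "snp_id": r.snp_id,
                "trait": r.trait,
                "chrom": "" if r.chrom is None else r.chrom,
                "gene": "" if r.gene is None else r.gene,
                "effect_allele": r.effect_allele,
                "other_allele": "" if r.other_allele is None else r.other_allele,
                "eaf": "" if r.eaf is None else repr(r.eaf),
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pvalue": "" if r.pvalue is None else repr(r.pvalue),
                "n": "" if r.n is None else str(r.n),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_results_table(results: Sequence, path: str | Path) -> None:
    """Serialize pooled MR results as an exposure-by-outcome TSV.

    One row per exposure; per outcome a ``beta``, ``se`` and ``p``
    column at full float precision, plus a ``display`` column rounded to
    3 decimals in the conventional "beta ± se" form.  Cells for pairs
    missing from ``results`` are left empty.
    """
    results = list(results)
    if not results:
        raise SummaryStatsError("no results to write")
    exposures: list[str] = []
    outcomes: list[str] = []
    for res in results:
        if res.exposure not in exposures:
            exposures.append(res.exposure)
        if res.outcome not in outcomes:
            outcomes.append(res.outcome)
    by_pair = {(res.exposure, res.outcome): res for res in results}
    rows = []
    for exposure in exposures:
        row: dict[str, object] = {"exposure": exposure}
        for outcome in outcomes:
            res = by_pair.get((exposure, outcome))
            if res is None:
                continue
            row[f"{outcome}|beta"] = repr(res.beta)
            row[f"{outcome}|se"] = repr(res.se)
            row[f"{outcome}|p"] = repr(res.p)
            row[f"{outcome}|display"] = f"{res.beta:.3f} ± {res.se:.3f} (p={res.p:.3f})"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV back; numeric columns parsed at full precision."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in frame.columns:
        if col.endswith(("|beta", "|se", "|p")):
            frame[col] = frame[col].map(lambda s: float(s) if s else math.nan)
    return frame
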