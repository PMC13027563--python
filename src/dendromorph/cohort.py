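"""Specimen data model, CSV input/output and per-taxon descriptive summaries.

A specimen is one male moth whose genitalia were measured on a permanent
slide: valva length (VL), harpe length (HL), aedeagus length measured along
a straight chord (AL_s) and along the dorsal arc (AL_a), aedeagus width (AW),
and the lengths of up to ten individual cornuti.  All measurements are in
millimetres.  The per-specimen cornuti length (CL) used by every downstream
index is the arithmetic mean of the recorded cornuti.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Taxon",
    "SpecimenRecord",
    "CohortTable",
    "SchemaError",
    "ValidationError",
    "read_specimen_table",
    "write_specimen_table",
    "cornuti_mean",
    "summarize_structure_by_taxon",
    "STRUCTURE_CODES",
    "MAX_CORNUTI",
]

#: Canonical reporting order for the six measured structures.
STRUCTURE_CODES = ("VL", "HL", "AL_s", "AL_a", "AW", "CL")

MAX_CORNUTI = 10

#: HL can approach VL in hybrids/sibiricus but a ratio beyond this is suspect.
_HL_VL_WARN_RATIO = 1.2


class SchemaError(ValueError):
    """A tabular input does not follow the expected CSV schema."""


class ValidationError(ValueError):
    """A specimen or cohort violates a measurement invariant."""


class Taxon(str, Enum):
    """Taxon assignment of a specimen.

    ``unknown`` is accepted on input (unidentified field material) but is
    never produced by any classifier in this package.
    """

    SIBIRICUS = "sibiricus"
    PINI = "pini"
    HYBRID = "hybrid"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, text: "str | Taxon") -> "Taxon":
        if isinstance(text, cls):
            return text
        try:
            return cls(str(text).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unrecognised taxon {text!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


#: Deterministic taxon ordering used in every summary table.
TAXON_ORDER = (Taxon.SIBIRICUS, Taxon.PINI, Taxon.HYBRID, Taxon.UNKNOWN)


@dataclass(frozen=True)
class SpecimenRecord:
    """One male's genitalia measurements (mm) plus provenance metadata.

    ``cornuti`` may be empty — cornuti are transferred to the female during
    copulation and can be genuinely absent from a slide — in which case the
    cornuti-dependent indices are simply unavailable for this specimen.
    """

    specimen_id: str
    taxon: Taxon
    valva_length: float
    harpe_length: float
    aedeagus_length_straight: float
    aedeagus_length_arc: float
    aedeagus_width: float
    cornuti: tuple[float, ...] = ()
    region: str = ""
    year: str = ""
    depository: str = ""

    def __post_init__(self) -> None:
        if not str(self.specimen_id):
            raise ValidationError("specimen_id must be a non-empty string")
        object.__setattr__(self, "taxon", Taxon.parse(self.taxon))
        object.__setattr__(self, "cornuti", tuple(float(c) for c in self.cornuti))
        for name in (
            "valva_length",
            "harpe_length",
            "aedeagus_length_straight",
            "aedeagus_length_arc",
            "aedeagus_width",
        ):
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: {name} must be a positive "
                    f"finite number, got {value!r}"
                )
        if self.aedeagus_length_arc < self.aedeagus_length_straight:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: aedeagus_length_arc "
                f"({self.aedeagus_length_arc}) must be >= "
                f"aedeagus_length_straight ({self.aedeagus_length_straight})"
            )
        if len(self.cornuti) > MAX_CORNUTI:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: at most {MAX_CORNUTI} cornuti "
                f"are measured per specimen, got {len(self.cornuti)}"
            )
        for c in self.cornuti:
            if not math.isfinite(c) or c <= 0:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: cornuti lengths must be "
                    f"positive, got {c!r}"
                )
        if self.harpe_length / self.valva_length > _HL_VL_WARN_RATIO:
            logger.warning(
                "specimen %r: harpe length exceeds %.0f%% of valva length "
                "(HL/VL = %.3f); check the measurements",
                self.specimen_id,
                _HL_VL_WARN_RATIO * 100,
                self.harpe_length / self.valva_length,
            )

    @property
    def has_cornuti(self) -> bool:
        return len(self.cornuti) > 0

    def scaled(self, k: float) -> "SpecimenRecord":
        """Return a copy with every measurement multiplied by ``k`` > 0."""
        if k <= 0:
            raise ValidationError("scale factor must be positive")
        return replace(
            self,
            valva_length=self.valva_length * k,
            harpe_length=self.harpe_length * k,
            aedeagus_length_straight=self.aedeagus_length_straight * k,
            aedeagus_length_arc=self.aedeagus_length_arc * k,
            aedeagus_width=self.aedeagus_width * k,
            cornuti=tuple(c * k for c in self.cornuti),
        )


def cornuti_mean(record: SpecimenRecord) -> float:
    """Per-specimen cornuti length CL: arithmetic mean of the measured cornuti.

    Ten cornuti are measured per specimen when present (five from each of the
    two symmetric groups on the vesica); their mean is the single CL scalar
    used by every cornuti-dependent index.
    """
    if not record.cornuti:
        raise ValidationError(
            f"specimen {record.specimen_id!r}: cornuti required to compute CL"
        )
    return sum(record.cornuti) / len(record.cornuti)


@dataclass(frozen=True)
class CohortTable:
    """An ordered, validated collection of specimens with unique identifiers."""

    records: tuple[SpecimenRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise ValidationError("a cohort must contain at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.specimen_id in seen:
                raise ValidationError(
                    f"duplicate specimen_id {rec.specimen_id!r} in cohort"
                )
            seen.add(rec.specimen_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def taxon_counts(self) -> dict[Taxon, int]:
        counts: dict[Taxon, int] = {}
        for rec in self.records:
            counts[rec.taxon] = counts.get(rec.taxon, 0) + 1
        return counts

    def subset(self, taxa: Sequence[Taxon]) -> "CohortTable":
        wanted = {Taxon.parse(t) for t in taxa}
        return CohortTable(tuple(r for r in self.records if r.taxon in wanted))

    def structure_values(self, rec: SpecimenRecord) -> dict[str, float | None]:
        """The six structure values of one record, keyed by STRUCTURE_CODES."""
        return {
            "VL": rec.valva_length,
            "HL": rec.harpe_length,
            "AL_s": rec.aedeagus_length_straight,
            "AL_a": rec.aedeagus_length_arc,
            "AW": rec.aedeagus_width,
            "CL": cornuti_mean(rec) if rec.has_cornuti else None,
        }


# --- CSV schema ---------------------------------------------------------

_META_COLUMNS = ("specimen_id", "taxon", "region", "year", "depository")
_MEASURE_COLUMNS = (
    "valva_length_mm",
    "harpe_length_mm",
    "aedeagus_length_straight_mm",
    "aedeagus_length_arc_mm",
    "aedeagus_width_mm",
)
_CORNUTI_COLUMNS = tuple(f"cornutus_{i:02d}_mm" for i in range(1, MAX_CORNUTI + 1))
CSV_COLUMNS = _META_COLUMNS + _MEASURE_COLUMNS + _CORNUTI_COLUMNS


def _record_from_row(row: pd.Series) -> SpecimenRecord:
    cornuti = []
    for col in _CORNUTI_COLUMNS:
        cell = row.get(col)
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            continue
        text = str(cell).strip()
        if not text:
            continue
        cornuti.append(float(text))

    def _opt(col: str) -> str:
        cell = row.get(col)
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            return ""
        return str(cell).strip()

    return SpecimenRecord(
        specimen_id=str(row["specimen_id"]).strip(),
        taxon=Taxon.parse(row["taxon"]),
        valva_length=float(row["valva_length_mm"]),
        harpe_length=float(row["harpe_length_mm"]),
        aedeagus_length_straight=float(row["aedeagus_length_straight_mm"]),
        aedeagus_length_arc=float(row["aedeagus_length_arc_mm"]),
        aedeagus_width=float(row["aedeagus_width_mm"]),
        cornuti=tuple(cornuti),
        region=_opt("region"),
        year=_opt("year"),
        depository=_opt("depository"),
    )


def read_specimen_table(path: str | Path, strict: bool = True) -> CohortTable:
    """Read a specimen CSV into a validated :class:`CohortTable`.

    In strict mode (the default, appropriate for quarantine diagnostics) the
    first invalid row aborts the read; in lenient mode invalid rows are
    dropped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    mandatory = _META_COLUMNS[:2] + _MEASURE_COLUMNS
    for col in mandatory:
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column {col!r} in {path}")
    records: list[SpecimenRecord] = []
    for _, row in frame.iterrows():
        try:
            records.append(_record_from_row(row))
        except (ValidationError, ValueError) as exc:
            if strict:
                if isinstance(exc, ValidationError):
                    raise
                raise ValidationError(
                    f"row with specimen_id {row.get('specimen_id')!r}: {exc}"
                ) from exc
            logger.warning(
                "dropping row with specimen_id %r: %s", row.get("specimen_id"), exc
            )
    return CohortTable(tuple(records))


def _fmt(value: float) -> str:
    # str() of a float is the shortest representation that round-trips exactly
    return str(float(value))


def write_specimen_table(cohort: CohortTable, path: str | Path) -> Path:
    """Write a cohort to CSV; ``read_specimen_table`` recovers it exactly."""
    path = Path(path)
    rows = []
    for rec in cohort:
        row: dict[str, str] = {
            "specimen_id": rec.specimen_id,
            "taxon": rec.taxon.value,
            "region": rec.region,
            "year": rec.year,
            "depository": rec.depository,
            "valva_length_mm": _fmt(rec.valva_length),
            "harpe_length_mm": _fmt(rec.harpe_length),
            "aedeagus_length_straight_mm": _fmt(rec.aedeagus_length_straight),
            "aedeagus_length_arc_mm": _fmt(rec.aedeagus_length_arc),
            "aedeagus_width_mm": _fmt(rec.aedeagus_width),
        }
        for i, col in enumerate(_CORNUTI_COLUMNS):
            row[col] = _fmt(rec.cornuti[i]) if i < len(rec.cornuti) else ""
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def summarize_structure_by_taxon(cohort: CohortTable) -> pd.DataFrame:
    """Per-taxon descriptive statistics of the six measured structures.

    Returns one row per (taxon, structure) with columns
    ``taxon, structure, n, mean, sd, min, max``.  The sample SD uses the
    n−1 denominator and is reported as NaN for n = 1.  CL rows count only
    specimens with at least one measured cornutus.
    """
    buckets: dict[tuple[str, str], list[float]] = {}
    present_taxa = [t for t in TAXON_ORDER if any(r.taxon == t for r in cohort)]
    for rec in cohort:
        values = cohort.structure_values(rec)
        for code in STRUCTURE_CODES:
            v = values[code]
            if v is not None:
                buckets.setdefault((rec.taxon.value, code), []).append(v)
    rows = []
    for taxon in present_taxa:
        for code in STRUCTURE_CODES:
            vals = buckets.get((taxon.value, code), [])
            n = len(vals)
            if n == 0:
                rows.append(
                    {"taxon": taxon.value, "structure": code, "n": 0,
                     "mean": math.nan, "sd": math.nan,
                     "min": math.nan, "max": math.nan}
                )
                continue
            series = pd.Series(vals, dtype=float)
            rows.append(
                {
                    "taxon": taxon.value,
                    "structure": code,
                    "n": n,
                    "mean": float(series.mean()),
                    "sd": float(series.std(ddof=1)) if n >= 2 else math.nan,
                    "min": float(series.min()),
                    "max": float(series.max()),
                }
            )
    return pd.DataFrame(rows, columns=["taxon", "structure", "n", "mean", "sd", "min", "max"])
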