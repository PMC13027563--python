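"""Operational identification of unknown specimens.

The published two-step decision rule:

1. ``HL/VL <= 0.32``  -> *D. pini* (the parental HL/VL ranges do not
   overlap, so this step is essentially error-free);
2. otherwise ``CGPI_straight <= 0.6705`` -> F1 hybrid, else *D. sibiricus*.

The HL/VL cut-point is the published one; the CGPI cut-point is derived as
the midpoint of the adjacent reference-interval extremes (hybrid max 0.664,
sibiricus min 0.677).  Each call is then cross-checked against the called
taxon's per-index reference intervals, yielding a confidence grade for
quarantine use: ``consistent`` (every available index in range),
``borderline`` (one out of range), ``conflicting`` (two or more out).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .cohort import CohortTable, Taxon, ValidationError
from .indices import (
    INDEX_KEYS,
    IndexProfile,
    cohort_index_table,
    compute_index_profile,
    profile_column,
)

__all__ = [
    "DEFAULT_HL_VL_THRESHOLD",
    "DEFAULT_CGPI_THRESHOLD",
    "ReferenceTable",
    "ClassificationResult",
    "load_builtin_reference_table",
    "build_reference_table",
    "reference_interval_flags",
    "classify_by_decision_rule",
    "classify_cohort",
]

#: Published HL/VL cut-point separating D. pini from the rest.
DEFAULT_HL_VL_THRESHOLD = 0.32
#: Derived CGPI_straight cut-point (midpoint of hybrid max and sibiricus min).
DEFAULT_CGPI_THRESHOLD = 0.6705


@dataclass(frozen=True)
class ReferenceTable:
    """Per (index, variant, taxon) mean/sd/min/max reference values."""

    frame: pd.DataFrame  # columns: index, variant, taxon, mean, sd, min, max, n

    def __post_init__(self) -> None:
        required = {"index", "variant", "taxon", "mean", "sd", "min", "max", "n"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"reference table missing columns {sorted(missing)}")
        bad = self.frame[
            (self.frame["min"] > self.frame["mean"])
            | (self.frame["mean"] > self.frame["max"])
        ]
        if len(bad):
            raise ValidationError("reference table violates min <= mean <= max")

    def taxa(self) -> list[str]:
        return list(pd.unique(self.frame["taxon"]))

    def interval(self, index: str, variant: str, taxon: str) -> tuple[float, float]:
        sel = self.frame[
            (self.frame["index"] == index)
            & (self.frame["variant"] == variant)
            & (self.frame["taxon"] == taxon)
        ]
        if sel.empty:
            raise ValidationError(
                f"no reference entry for ({index}, {variant}, {taxon})"
            )
        row = sel.iloc[0]
        return float(row["min"]), float(row["max"])

    def mean_profile(self, taxon: str) -> IndexProfile:
        """An index profile sitting at the taxon's reference means."""
        values: dict[str, float] = {}
        for index, variant in INDEX_KEYS:
            sel = self.frame[
                (self.frame["index"] == index)
                & (self.frame["variant"] == variant)
                & (self.frame["taxon"] == taxon)
            ]
            if not sel.empty:
                values[profile_column(index, variant)] = float(sel.iloc[0]["mean"])
        if "hl_vl" not in values:
            raise ValidationError(f"taxon {taxon!r} absent from reference table")
        return IndexProfile(specimen_id=f"{taxon}-reference-mean", **values)


def load_builtin_reference_table() -> ReferenceTable:
    """The reference intervals shipped with the package."""
    with resources.files("dendromorph.data").joinpath(
        "reference_intervals.csv"
    ).open("r") as handle:
        frame = pd.read_csv(handle, comment="#")
    return ReferenceTable(frame=frame)


def build_reference_table(cohort: CohortTable) -> ReferenceTable:
    """Recompute a reference table from a labelled cohort (each taxon n >= 2).

    This is how users regenerate the published-style reference intervals from
    their own material.
    """
    counts = cohort.taxon_counts()
    for taxon, n in counts.items():
        if taxon is Taxon.UNKNOWN:
            raise ValidationError("cohort contains unlabelled specimens")
        if n < 2:
            raise ValidationError(
                f"taxon {taxon.value!r} has n = {n}; at least 2 specimens are "
                "needed for a defined SD"
            )
    table = cohort_index_table(cohort)
    table = table[table["n"] > 0].reset_index(drop=True)
    return ReferenceTable(frame=table)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of the decision rule for one specimen."""

    specimen_id: str
    call: Taxon
    rule_path: tuple[tuple[str, float, str], ...]  # (index, threshold, direction)
    range_flags: Mapping[str, bool]  # profile column -> inside called taxon's interval
    confidence: str  # consistent | borderline | conflicting

    @property
    def n_out_of_range(self) -> int:
        return sum(not ok for ok in self.range_flags.values())


def reference_interval_flags(
    profile: IndexProfile,
    taxon: Taxon | str,
    table: ReferenceTable,
) -> dict[str, bool]:
    """Flag each available index of ``profile`` against the taxon's intervals.

    ``True`` means inside the inclusive [min, max] reference interval of the
    given taxon; indices absent from the profile are omitted.
    """
    taxon = Taxon.parse(taxon if isinstance(taxon, str) else taxon.value)
    if taxon.value not in table.taxa():
        raise ValidationError(f"taxon {taxon.value!r} absent from reference table")
    flags: dict[str, bool] = {}
    for index, variant in INDEX_KEYS:
        col = profile_column(index, variant)
        value = getattr(profile, col)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        try:
            lo, hi = table.interval(index, variant, taxon.value)
        except ValidationError:
            continue
        flags[col] = bool(lo <= value <= hi)
    return flags


def _confidence(flags: Mapping[str, bool]) -> str:
    n_out = sum(not ok for ok in flags.values())
    if n_out == 0:
        return "consistent"
    if n_out == 1:
        return "borderline"
    return "conflicting"


def classify_by_decision_rule(
    profile: IndexProfile,
    hl_vl_threshold: float = DEFAULT_HL_VL_THRESHOLD,
    cgpi_threshold: float = DEFAULT_CGPI_THRESHOLD,
    table: ReferenceTable | None = None,
) -> ClassificationResult:
    """Apply the two-step decision rule and grade the call's consistency.

    Both thresholds are inclusive on the left branch.  The CGPI step uses the
    straight-line variant; if it is needed but absent (no cornuti measured)
    an error explains the remedy.
    """
    if table is None:
        table = load_builtin_reference_table()
    if profile.hl_vl is None:
        raise ValidationError("profile lacks hl_vl; it is required by the rule")

    if profile.hl_vl <= hl_vl_threshold:
        call = Taxon.PINI
        rule_path = (("hl_vl", hl_vl_threshold, "<="),)
    else:
        if profile.cgpi_straight is None:
            raise ValidationError(
                f"specimen {profile.specimen_id!r}: CGPI (straight) is required "
                "to separate sibiricus from hybrids but no cornuti were "
                "measured; measure the cornuti or retrain the decision tree "
                "without CGPI"
            )
        if profile.cgpi_straight <= cgpi_threshold:
            call = Taxon.HYBRID
            rule_path = (
                ("hl_vl", hl_vl_threshold, ">"),
                ("cgpi_straight", cgpi_threshold, "<="),
            )
        else:
            call = Taxon.SIBIRICUS
            rule_path = (
                ("hl_vl", hl_vl_threshold, ">"),
                ("cgpi_straight", cgpi_threshold, ">"),
            )
    flags = reference_interval_flags(profile, call, table)
    return ClassificationResult(
        specimen_id=profile.specimen_id,
        call=call,
        rule_path=rule_path,
        range_flags=flags,
        confidence=_confidence(flags),
    )


def classify_cohort(
    cohort: CohortTable,
    hl_vl_threshold: float = DEFAULT_HL_VL_THRESHOLD,
    cgpi_threshold: float = DEFAULT_CGPI_THRESHOLD,
    table: ReferenceTable | None = None,
) -> pd.DataFrame:
    """Classification report for every specimen of a cohort.

    Columns: ``specimen_id, labelled_taxon, call, hl_vl, cgpi_straight,
    rule_path, n_flags_out, confidence``.
    """
    if table is None:
        table = load_builtin_reference_table()
    rows = []
    for rec in cohort:
        profile = compute_index_profile(rec)
        result = classify_by_decision_rule(
            profile, hl_vl_threshold, cgpi_threshold, table
        )
        rows.append(
            {
                "specimen_id": rec.specimen_id,
                "labelled_taxon": rec.taxon.value,
                "call": result.call.value,
                "hl_vl": profile.hl_vl,
                "cgpi_straight": profile.cgpi_straight,
                "rule_path": " -> ".join(
                    f"{idx}{op}{thr:g}" for idx, thr, op in result.rule_path
                ),
                "n_flags_out": result.n_out_of_range,
                "confidence": result.confidence,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "specimen_id",
            "labelled_taxon",
            "call",
            "hl_vl",
            "cgpi_straight",
            "rule_path",
            "n_flags_out",
            "confidence",
        ],
    )
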