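"""The four diagnostic genitalia ratio indices and their cohort summaries.

Indices (all dimensionless ratios of millimetre measurements):

* ``HL/VL``  — harpe length over valva length; the single strongest
  species discriminator.
* ``AW/AL``  — aedeagus width over aedeagus length.
* ``CL/AL``  — mean cornuti length over aedeagus length.
* ``CGPI``   — combined genital proportion index,
  ``(VL + HL) / (AL + CL)``.

Every aedeagus-length-dependent index comes in two variants, computed with
the straight-chord length (``straight``) and with the arc length (``arc``).
Cohort-level statistics are means of per-specimen ratios, not ratios of
means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .cohort import (
    CohortTable,
    SpecimenRecord,
    Taxon,
    TAXON_ORDER,
    ValidationError,
    cornuti_mean,
)

__all__ = [
    "IndexProfile",
    "INDEX_KEYS",
    "compute_index_profile",
    "profiles_frame",
    "cohort_index_table",
    "percent_difference",
    "arc_excess_summary",
]

#: Canonical (index, variant) pairs in reporting order.  ``variant`` is
#: ``na`` for HL/VL, which does not involve the aedeagus.
INDEX_KEYS: tuple[tuple[str, str], ...] = (
    ("hl_vl", "na"),
    ("aw_al", "straight"),
    ("aw_al", "arc"),
    ("cl_al", "straight"),
    ("cl_al", "arc"),
    ("cgpi", "straight"),
    ("cgpi", "arc"),
)

#: Column names of the per-specimen profile frame, in order.
PROFILE_COLUMNS = (
    "hl_vl",
    "aw_al_straight",
    "aw_al_arc",
    "cl_al_straight",
    "cl_al_arc",
    "cgpi_straight",
    "cgpi_arc",
)


def profile_column(index: str, variant: str) -> str:
    return "hl_vl" if index == "hl_vl" else f"{index}_{variant}"


@dataclass(frozen=True)
class IndexProfile:
    """The diagnostic index values of one specimen.

    The cornuti-dependent fields (``cl_al_*``, ``cgpi_*``) are ``None`` when
    the specimen has no measured cornuti.
    """

    specimen_id: str
    hl_vl: float
    aw_al_straight: float
    aw_al_arc: float
    cl_al_straight: float | None = None
    cl_al_arc: float | None = None
    cgpi_straight: float | None = None
    cgpi_arc: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {col: getattr(self, col) for col in PROFILE_COLUMNS}

    def get(self, index: str, variant: str) -> float | None:
        return getattr(self, profile_column(index, variant))


def compute_index_profile(record: SpecimenRecord) -> IndexProfile:
    """Compute the four indices (seven values) for one specimen."""
    vl = record.valva_length
    hl = record.harpe_length
    al_s = record.aedeagus_length_straight
    al_a = record.aedeagus_length_arc
    aw = record.aedeagus_width
    if record.has_cornuti:
        cl = cornuti_mean(record)
        cl_al_s: float | None = cl / al_s
        cl_al_a: float | None = cl / al_a
        cgpi_s: float | None = (vl + hl) / (al_s + cl)
        cgpi_a: float | None = (vl + hl) / (al_a + cl)
    else:
        cl_al_s = cl_al_a = cgpi_s = cgpi_a = None
    return IndexProfile(
        specimen_id=record.specimen_id,
        hl_vl=hl / vl,
        aw_al_straight=aw / al_s,
        aw_al_arc=aw / al_a,
        cl_al_straight=cl_al_s,
        cl_al_arc=cl_al_a,
        cgpi_straight=cgpi_s,
        cgpi_arc=cgpi_a,
    )


def profiles_frame(cohort: CohortTable) -> pd.DataFrame:
    """Per-specimen index values as a DataFrame.

    Columns: ``specimen_id, taxon`` plus :data:`PROFILE_COLUMNS`; missing
    cornuti-dependent values appear as NaN.
    """
    rows = []
    for rec in cohort:
        prof = compute_index_profile(rec)
        row: dict[str, object] = {"specimen_id": rec.specimen_id, "taxon": rec.taxon.value}
        for col, val in prof.as_dict().items():
            row[col] = math.nan if val is None else val
        rows.append(row)
    return pd.DataFrame(rows, columns=["specimen_id", "taxon", *PROFILE_COLUMNS])


def cohort_index_table(cohort: CohortTable) -> pd.DataFrame:
    """Per-taxon summary of per-specimen indices (mean of ratios).

    One row per (taxon, index, variant) with ``n, mean, sd, min, max``; this
    is the construction behind a reference-interval table.  Rows whose index
    could not be computed for any specimen of the taxon have n = 0 and NaN
    statistics.
    """
    frame = profiles_frame(cohort)
    present = [t.value for t in TAXON_ORDER if (frame["taxon"] == t.value).any()]
    rows = []
    for taxon in present:
        sub = frame[frame["taxon"] == taxon]
        for index, variant in INDEX_KEYS:
            col = sub[profile_column(index, variant)].dropna()
            n = int(col.size)
            rows.append(
                {
                    "taxon": taxon,
                    "index": index,
                    "variant": variant,
                    "n": n,
                    "mean": float(col.mean()) if n else math.nan,
                    "sd": float(col.std(ddof=1)) if n >= 2 else math.nan,
                    "min": float(col.min()) if n else math.nan,
                    "max": float(col.max()) if n else math.nan,
                }
            )
    return pd.DataFrame(
        rows, columns=["taxon", "index", "variant", "n", "mean", "sd", "min", "max"]
    )


def percent_difference(reference_mean: float, other_mean: float) -> float:
    """Percent by which ``other_mean`` falls short of ``reference_mean``.

    ``100 * (reference - other) / reference``; the reference (first argument)
    is the larger species mean, so "harpe is 74% longer in the reference"
    style statements come out directly.
    """
    if reference_mean <= 0:
        raise ValidationError("reference mean must be positive")
    return 100.0 * (reference_mean - other_mean) / reference_mean


def arc_excess_summary(
    source: CohortTable | Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """Percent excess of arc over straight aedeagus length, per taxon.

    ``source`` is either a cohort (per-taxon means are computed from it) or a
    mapping ``taxon -> (mean AL_straight, mean AL_arc)``.  Returns one row per
    taxon plus a ``grand`` row holding the unweighted mean of the per-taxon
    excesses.
    """
    if isinstance(source, CohortTable):
        means: dict[str, tuple[float, float]] = {}
        for taxon in TAXON_ORDER:
            recs = [r for r in source if r.taxon == taxon]
            if not recs:
                continue
            al_s = sum(r.aedeagus_length_straight for r in recs) / len(recs)
            al_a = sum(r.aedeagus_length_arc for r in recs) / len(recs)
            means[taxon.value] = (al_s, al_a)
    else:
        means = {str(k): (float(v[0]), float(v[1])) for k, v in source.items()}
    rows = []
    for taxon, (al_s, al_a) in means.items():
        if al_s <= 0:
            raise ValidationError(f"taxon {taxon!r}: straight length must be positive")
        rows.append(
            {"taxon": taxon, "percent_excess": 100.0 * (al_a - al_s) / al_s}
        )
    if not rows:
        raise ValidationError("no taxa with aedeagus measurements")
    grand = sum(r["percent_excess"] for r in rows) / len(rows)
    rows.append({"taxon": "grand", "percent_excess": grand})
    return pd.DataFrame(rows, columns=["taxon", "percent_excess"])
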