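"""Synthetic specimen cohorts calibrated to the published per-taxon moments.

The raw per-specimen measurements behind the published summary statistics
are not deposited, so this module generates cohorts with the same
statistical structure: three taxa (33 *D. sibiricus*, 33 *D. pini*, 4 F1
hybrids), per-structure normal variation at the printed means and SDs,
within-taxon cross-structure correlation, and an arc length that exceeds the
straight length by a taxon-specific multiplicative factor.

Two truncation layers keep draws biologically plausible:

* per-structure bounds (mean +- 3.5 SD, floored at 0.05 mm), and
* per-taxon index envelopes at the published reference [min, max] for HL/VL
  and CGPI_straight — the two indices the published decision rule uses.
  The parental HL/VL reference ranges do not overlap, and the envelopes
  make the generated cohorts honour that, exactly as the real material did.

The within-taxon harpe-valva correlation (0.65) is calibrated so that the
pooled 70-specimen harpe-on-valva regression reproduces the published line;
the cornuti-width correlation (0.16) likewise preserves the sign of the
pooled negative cornuti relationships.  Remaining pairs default to 0.3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortTable, SpecimenRecord, Taxon, ValidationError
from .indices import compute_index_profile

__all__ = [
    "STRUCT5",
    "TaxonParameterSet",
    "SimulationConfig",
    "default_parameters",
    "synthesize_cohort",
    "synthesize_cornuti_set",
    "replicate_seeds",
]

#: Order of the jointly drawn structures (arc length is derived, not drawn).
STRUCT5 = ("VL", "HL", "AL_s", "AW", "CL")

_STRUCT_IDX = {s: i for i, s in enumerate(STRUCT5)}
_POSITIVITY_FLOOR_MM = 0.05
_CORNUTI_FLOOR_MM = 0.01
_MAX_REDRAWS = 10_000


def _correlation_matrix(
    hl_vl_rho: float = 0.65, cl_aw_rho: float = 0.16, base_rho: float = 0.3
) -> np.ndarray:
    corr = np.full((5, 5), base_rho)
    np.fill_diagonal(corr, 1.0)
    i, j = _STRUCT_IDX["VL"], _STRUCT_IDX["HL"]
    corr[i, j] = corr[j, i] = hl_vl_rho
    i, j = _STRUCT_IDX["AW"], _STRUCT_IDX["CL"]
    corr[i, j] = corr[j, i] = cl_aw_rho
    return corr


@dataclass(frozen=True)
class TaxonParameterSet:
    """Generative moments for one taxon.

    ``means``/``sds`` cover the five jointly drawn structures (mm); the arc
    length is generated as ``AL_s * arc_factor * (1 + eps)`` with ``eps``
    mean-zero of SD ``arc_factor_cv``, floored so that arc > straight.
    ``index_envelopes`` maps an index profile column to an inclusive
    [min, max] acceptance interval; ``structure_bounds`` likewise bounds each
    drawn structure.  ``cornuti_within_cv`` is the coefficient of variation
    of individual cornuti around the specimen's mean cornuti length.
    """

    taxon: Taxon
    means: dict[str, float]
    sds: dict[str, float]
    arc_factor: float
    arc_factor_cv: float = 0.03
    correlations: np.ndarray = field(default_factory=_correlation_matrix)
    structure_bounds: dict[str, tuple[float, float]] | None = None
    index_envelopes: dict[str, tuple[float, float]] | None = None
    cornuti_within_cv: float = 0.10
    n_cornuti: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxon", Taxon.parse(self.taxon))
        for s in STRUCT5:
            if s not in self.means or s not in self.sds:
                raise ValidationError(f"missing moment for structure {s!r}")
            if self.sds[s] < 0:
                raise ValidationError(f"negative SD for structure {s!r}")
        if self.arc_factor <= 1.0:
            raise ValidationError("arc_factor must exceed 1")
        corr = np.asarray(self.correlations, dtype=float)
        if corr.shape != (5, 5) or not np.allclose(corr, corr.T):
            raise ValidationError("correlation matrix must be symmetric 5x5")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValidationError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValidationError("correlation matrix must be positive semidefinite")
        object.__setattr__(self, "correlations", corr)

    def covariance(self) -> np.ndarray:
        d = np.array([self.sds[s] for s in STRUCT5])
        return self.correlations * np.outer(d, d)

    def default_bounds(self) -> dict[str, tuple[float, float]]:
        if self.structure_bounds is not None:
            return self.structure_bounds
        return {
            s: (
                max(_POSITIVITY_FLOOR_MM, self.means[s] - 3.5 * self.sds[s]),
                self.means[s] + 3.5 * self.sds[s],
            )
            for s in STRUCT5
        }


@dataclass(frozen=True)
class SimulationConfig:
    """Seeded design of a synthetic cohort."""

    seed: int
    n_per_taxon: dict[Taxon, int] = field(
        default_factory=lambda: {Taxon.SIBIRICUS: 33, Taxon.PINI: 33, Taxon.HYBRID: 4}
    )
    parameters: dict[Taxon, TaxonParameterSet] | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        counts = {Taxon.parse(t.value if isinstance(t, Taxon) else t): int(n)
                  for t, n in self.n_per_taxon.items()}
        for taxon, n in counts.items():
            if n < 1:
                raise ValidationError(f"taxon {taxon.value!r}: n must be >= 1")
        object.__setattr__(self, "n_per_taxon", counts)
        params = self.parameters if self.parameters is not None else default_parameters()
        for taxon in counts:
            if taxon not in params:
                raise ValidationError(f"no parameters for taxon {taxon.value!r}")
        object.__setattr__(self, "parameters", params)
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")


# Published per-taxon structure moments (mm): mean, SD for VL, HL, AL_s, AW,
# CL; arc factor = mean arc length / mean straight length.
_PRINTED_MOMENTS: dict[Taxon, dict[str, tuple[float, float]]] = {
    Taxon.SIBIRICUS: {
        "VL": (2.002, 0.226),
        "HL": (1.312, 0.200),
        "AL_s": (3.712, 0.204),
        "AW": (0.798, 0.080),
        "CL": (0.188, 0.046),
    },
    Taxon.PINI: {
        "VL": (1.356, 0.112),
        "HL": (0.339, 0.055),
        "AL_s": (2.663, 0.200),
        "AW": (0.576, 0.052),
        "CL": (0.243, 0.027),
    },
    Taxon.HYBRID: {
        "VL": (1.609, 0.036),
        "HL": (0.608, 0.142),
        "AL_s": (3.315, 0.181),
        "AW": (0.619, 0.078),
        "CL": (0.259, 0.010),
    },
}

_PRINTED_ARC_MEANS: dict[Taxon, float] = {
    Taxon.SIBIRICUS: 4.844,
    Taxon.PINI: 3.295,
    Taxon.HYBRID: 4.194,
}

# Reference-interval envelopes for the two rule-relevant indices.
_INDEX_ENVELOPES: dict[Taxon, dict[str, tuple[float, float]]] = {
    Taxon.SIBIRICUS: {"hl_vl": (0.484, 0.847), "cgpi_straight": (0.677, 1.031)},
    Taxon.PINI: {"hl_vl": (0.149, 0.316), "cgpi_straight": (0.453, 0.736)},
    Taxon.HYBRID: {"hl_vl": (0.317, 0.503), "cgpi_straight": (0.568, 0.664)},
}


def default_parameters() -> dict[Taxon, TaxonParameterSet]:
    """The built-in generative parameters for the three study taxa."""
    params: dict[Taxon, TaxonParameterSet] = {}
    for taxon, moments in _PRINTED_MOMENTS.items():
        means = {s: m for s, (m, _) in moments.items()}
        sds = {s: sd for s, (_, sd) in moments.items()}
        params[taxon] = TaxonParameterSet(
            taxon=taxon,
            means=means,
            sds=sds,
            arc_factor=_PRINTED_ARC_MEANS[taxon] / means["AL_s"],
            index_envelopes=dict(_INDEX_ENVELOPES[taxon]),
        )
    return params


def synthesize_cornuti_set(
    rng: np.random.Generator, cl_mean: float, k: int = 10, cv: float = 0.10
) -> tuple[float, ...]:
    """Draw ``k`` individual cornuti lengths around a specimen-level mean.

    Draws are normal with coefficient of variation ``cv`` and floored at
    0.01 mm; their mean converges to ``cl_mean`` as ``k`` grows.
    """
    if cl_mean <= 0:
        raise ValidationError("cl_mean must be positive")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    draws = rng.normal(cl_mean, cv * cl_mean, size=k)
    return tuple(float(max(_CORNUTI_FLOOR_MM, d)) for d in draws)


def _draw_specimen(
    rng: np.random.Generator,
    params: TaxonParameterSet,
    specimen_id: str,
) -> SpecimenRecord:
    mean_vec = np.array([params.means[s] for s in STRUCT5])
    cov = params.covariance()
    bounds = params.default_bounds()
    envelopes = params.index_envelopes or {}
    degenerate = np.allclose(cov, 0.0)

    for _ in range(_MAX_REDRAWS):
        if degenerate:
            draw = mean_vec.copy()
        else:
            draw = rng.multivariate_normal(mean_vec, cov)
        if any(
            not (bounds[s][0] <= draw[_STRUCT_IDX[s]] <= bounds[s][1])
            for s in STRUCT5
        ):
            continue
        eps = rng.normal(0.0, params.arc_factor_cv)
        factor = max(params.arc_factor * (1.0 + eps), 1.001)
        al_s = float(draw[_STRUCT_IDX["AL_s"]])
        cornuti = synthesize_cornuti_set(
            rng,
            float(draw[_STRUCT_IDX["CL"]]),
            k=params.n_cornuti,
            cv=params.cornuti_within_cv,
        )
        record = SpecimenRecord(
            specimen_id=specimen_id,
            taxon=params.taxon,
            valva_length=float(draw[_STRUCT_IDX["VL"]]),
            harpe_length=float(draw[_STRUCT_IDX["HL"]]),
            aedeagus_length_straight=al_s,
            aedeagus_length_arc=al_s * factor,
            aedeagus_width=float(draw[_STRUCT_IDX["AW"]]),
            cornuti=cornuti,
            region="synthetic",
            year="",
            depository="in silico",
        )
        if envelopes and not degenerate:
            profile = compute_index_profile(record)
            ok = all(
                lo <= getattr(profile, col) <= hi
                for col, (lo, hi) in envelopes.items()
                if getattr(profile, col) is not None
            )
            if not ok:
                continue
        return record
    raise RuntimeError(
        f"could not draw an admissible specimen for {params.taxon.value!r} "
        f"within {_MAX_REDRAWS} attempts; check bounds/envelopes"
    )


def synthesize_cohort(config: SimulationConfig) -> CohortTable:
    """Generate one cohort; deterministic given the config's seed."""
    rng = np.random.default_rng(config.seed)
    records: list[SpecimenRecord] = []
    for taxon in (Taxon.SIBIRICUS, Taxon.PINI, Taxon.HYBRID, Taxon.UNKNOWN):
        n = config.n_per_taxon.get(taxon)
        if not n:
            continue
        params = config.parameters[taxon]
        for i in range(1, n + 1):
            records.append(
                _draw_specimen(rng, params, f"{taxon.value[:3]}_{i:03d}")
            )
    return CohortTable(tuple(records))


def config_from_dict(spec: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain dict (JSON-friendly).

    Recognised keys: ``seed`` (required), ``n_per_taxon`` (taxon name ->
    count), ``replicates``, and ``parameters`` — per-taxon override blocks
    whose entries (``means``, ``sds``, ``arc_factor``, ``arc_factor_cv``,
    ``cornuti_within_cv``, ``n_cornuti``) replace the defaults; unlisted
    fields keep their default values.
    """
    if "seed" not in spec:
        raise ValidationError("config requires a 'seed'")
    n_per_taxon = {
        Taxon.parse(t): int(n)
        for t, n in spec.get(
            "n_per_taxon", {"sibiricus": 33, "pini": 33, "hybrid": 4}
        ).items()
    }
    params = default_parameters()
    for taxon_name, block in (spec.get("parameters") or {}).items():
        taxon = Taxon.parse(taxon_name)
        base = params[taxon]
        params[taxon] = TaxonParameterSet(
            taxon=taxon,
            means={**base.means, **block.get("means", {})},
            sds={**base.sds, **block.get("sds", {})},
            arc_factor=float(block.get("arc_factor", base.arc_factor)),
            arc_factor_cv=float(block.get("arc_factor_cv", base.arc_factor_cv)),
            correlations=np.asarray(
                block.get("correlations", base.correlations), dtype=float
            ),
            structure_bounds=base.structure_bounds,
            index_envelopes=base.index_envelopes,
            cornuti_within_cv=float(
                block.get("cornuti_within_cv", base.cornuti_within_cv)
            ),
            n_cornuti=int(block.get("n_cornuti", base.n_cornuti)),
        )
    return SimulationConfig(
        seed=int(spec["seed"]),
        n_per_taxon=n_per_taxon,
        parameters=params,
        replicates=int(spec.get("replicates", 1)),
    )


def replicate_seeds(base_seed: int, n_replicates: int) -> list[int]:
    """Consecutive per-replicate seeds derived from a base seed (< 2^31)."""
    return [int((base_seed + i) % (2**31 - 1)) for i in range(n_replicates)]
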