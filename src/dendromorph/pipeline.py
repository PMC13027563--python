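"""End-to-end analysis pipeline and report rendering.

Mirrors the published analysis sequence on a given or simulated cohort:
descriptive statistics -> pairwise Mann-Whitney comparisons with compact
letter displays -> pooled regressions -> two-group discriminant analysis
(parental species only) -> chi-square decision tree (all taxa) ->
decision-rule classification.  Stages degrade gracefully: a stage that
cannot run (e.g. cornuti-dependent analyses on a cohort without cornuti) is
marked skipped with a reason and the pipeline continues.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Any

import pandas as pd

from .cohort import CohortTable, Taxon, summarize_structure_by_taxon
from .classify import classify_cohort
from .discriminant import backward_stepwise_select, f_remove_table, fit_two_group_lda
from .indices import (
    INDEX_KEYS,
    arc_excess_summary,
    cohort_index_table,
    profile_column,
    profiles_frame,
)
from .simulate import SimulationConfig, synthesize_cohort
from .stats import fit_linear_regression, mann_whitney, pairwise_letter_display
from .tree import fit_tree, tree_to_text

logger = logging.getLogger(__name__)

__all__ = ["PipelineReport", "run_full_pipeline", "render_report"]

#: Pooled structure-on-structure regressions reported for the whole cohort:
#: (response, predictor) pairs over per-specimen structure values.
_REGRESSION_PAIRS = (
    ("HL", "VL"),
    ("AW", "AL_s"),
    ("AW", "AL_a"),
    ("CL", "AW"),
    ("CL", "AL_s"),
    ("CL", "AL_a"),
)


@dataclass
class StageResult:
    name: str
    status: str  # ok | skipped | failed
    payload: Any = None
    reason: str = ""
    seconds: float = 0.0


@dataclass
class PipelineReport:
    """All artifacts of one pipeline run plus a provenance block."""

    stages: dict[str, StageResult] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def section(self, name: str) -> Any:
        return self.stages[name].payload

    def status(self, name: str) -> str:
        return self.stages[name].status


def _structure_frame(cohort: CohortTable) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        row = {"specimen_id": rec.specimen_id, "taxon": rec.taxon.value}
        row.update(cohort.structure_values(rec))
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_comparisons(cohort: CohortTable, alpha: float) -> pd.DataFrame:
    struct = _structure_frame(cohort)
    profs = profiles_frame(cohort)
    taxa = [t.value for t in (Taxon.SIBIRICUS, Taxon.PINI, Taxon.HYBRID)
            if (struct["taxon"] == t.value).any()]
    rows = []
    targets = [("structure", c) for c in ("VL", "HL", "AL_s", "AL_a", "AW", "CL")]
    targets += [
        ("index", profile_column(i, v)) for i, v in INDEX_KEYS
    ]
    for kind, col in targets:
        frame = struct if kind == "structure" else profs
        groups = {
            t: frame.loc[frame["taxon"] == t, col].dropna().to_list() for t in taxa
        }
        groups = {t: g for t, g in groups.items() if g}
        if len(groups) < 2:
            continue
        display = pairwise_letter_display(groups, alpha=alpha)
        names = list(groups)
        for i, g1 in enumerate(names):
            for g2 in names[i + 1:]:
                res = mann_whitney(groups[g1], groups[g2])
                rows.append(
                    {
                        "variable": col,
                        "kind": kind,
                        "group_1": g1,
                        "group_2": g2,
                        "n1": res.n1,
                        "n2": res.n2,
                        "U": res.u_statistic,
                        "Z": res.z_statistic,
                        "p": res.p_two_sided,
                        "method": res.method.value,
                        f"significant_at_{alpha:g}": res.p_two_sided <= alpha,
                        "letters_1": display.letters[g1],
                        "letters_2": display.letters[g2],
                    }
                )
    return pd.DataFrame(rows)


def _stage_regressions(cohort: CohortTable) -> pd.DataFrame:
    struct = _structure_frame(cohort)
    rows = []
    for y_col, x_col in _REGRESSION_PAIRS:
        sub = struct[[x_col, y_col]].dropna()
        if len(sub) < 3:
            continue
        fit = fit_linear_regression(sub[x_col].to_list(), sub[y_col].to_list())
        rows.append(
            {
                "response": y_col,
                "predictor": x_col,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n": fit.n,
                "p_slope": fit.p_slope,
            }
        )
    return pd.DataFrame(rows)


def _stage_discriminant(cohort: CohortTable, p_remove: float) -> dict[str, pd.DataFrame]:
    parental = cohort.subset([Taxon.SIBIRICUS, Taxon.PINI])
    struct = _structure_frame(parental).dropna(subset=["CL"])
    group = struct["taxon"].to_list()
    out: dict[str, pd.DataFrame] = {}

    structure_vars = ["VL", "HL", "AL_s", "AL_a", "AW", "CL"]
    model = fit_two_group_lda(struct, group, structure_vars)
    out["structures_f_remove"] = pd.DataFrame(
        [
            {"variable": e.variable, "f_remove": e.f_remove, "p_value": e.p_value}
            for e in f_remove_table(model, struct, group)
        ]
    ).sort_values("f_remove", ascending=False, kind="stable").reset_index(drop=True)

    profs = profiles_frame(parental).dropna()
    pg = profs["taxon"].to_list()
    index_vars = [profile_column(i, v) for i, v in INDEX_KEYS]
    model1 = fit_two_group_lda(profs, pg, index_vars)
    out["indices_model1_f_remove"] = pd.DataFrame(
        [
            {"variable": e.variable, "f_remove": e.f_remove, "p_value": e.p_value}
            for e in f_remove_table(model1, profs, pg)
        ]
    ).sort_values("f_remove", ascending=False, kind="stable").reset_index(drop=True)

    no_hlvl = [v for v in index_vars if v != "hl_vl"]
    model2, trace = backward_stepwise_select(profs, pg, no_hlvl, p_remove=p_remove)
    out["indices_model2_trace"] = trace
    if model2 is not None:
        out["indices_model2_f_remove"] = pd.DataFrame(
            [
                {"variable": e.variable, "f_remove": e.f_remove, "p_value": e.p_value}
                for e in f_remove_table(model2, profs, pg)
            ]
        ).sort_values("f_remove", ascending=False, kind="stable").reset_index(drop=True)
    return out


def run_full_pipeline(
    cohort: CohortTable | None = None,
    config: SimulationConfig | None = None,
    alpha: float = 0.01,
    p_remove: float = 0.10,
    tree_alpha: float = 0.05,
    min_leaf: int = 2,
) -> PipelineReport:
    """Run the full analysis sequence on a cohort or a simulated one."""
    if cohort is None:
        if config is None:
            raise ValueError("provide a cohort or a simulation config")
        cohort = synthesize_cohort(config)

    report = PipelineReport()
    config_desc = repr(config) if config is not None else "external-cohort"
    report.provenance = {
        "seed": str(config.seed) if config is not None else "",
        "config_hash": hashlib.sha256(config_desc.encode()).hexdigest()[:16],
        "package_version": _pkg_version("dendromorph"),
        "n_specimens": str(len(cohort)),
    }

    def run_stage(name, fn, *, skip_reason: str = ""):
        start = time.perf_counter()
        if skip_reason:
            report.stages[name] = StageResult(name, "skipped", reason=skip_reason)
            logger.info("stage %s skipped: %s", name, skip_reason)
            return
        try:
            payload = fn()
            report.stages[name] = StageResult(
                name, "ok", payload, seconds=time.perf_counter() - start
            )
            logger.info("stage %s ok (%.2fs)", name, time.perf_counter() - start)
        except Exception as exc:  # stage isolation is the contract here
            report.stages[name] = StageResult(
                name, "failed", reason=str(exc), seconds=time.perf_counter() - start
            )
            logger.warning("stage %s failed: %s", name, exc)

    any_cornuti = any(rec.has_cornuti for rec in cohort)
    taxa_present = set(cohort.taxon_counts())
    parental_ok = (
        Taxon.SIBIRICUS in taxa_present and Taxon.PINI in taxa_present
    )

    run_stage("descriptives", lambda: summarize_structure_by_taxon(cohort))
    run_stage("arc_excess", lambda: arc_excess_summary(cohort))
    run_stage("index_table", lambda: cohort_index_table(cohort))
    run_stage("comparisons", lambda: _stage_comparisons(cohort, alpha))
    run_stage("regressions", lambda: _stage_regressions(cohort))
    run_stage(
        "discriminant",
        lambda: _stage_discriminant(cohort, p_remove),
        skip_reason=(
            "" if (parental_ok and any_cornuti)
            else "requires both parental species and cornuti measurements"
        ),
    )

    def tree_stage():
        profs = profiles_frame(cohort)
        cols = [profile_column(i, v) for i, v in INDEX_KEYS]
        if not any_cornuti:
            cols = ["hl_vl", "aw_al_straight", "aw_al_arc"]
            profs = profs.dropna(subset=cols)
        else:
            profs = profs.dropna(subset=cols)
        model = fit_tree(
            profs[cols], profs["taxon"].to_list(),
            min_leaf=min_leaf, alpha_split=tree_alpha,
        )
        return model

    run_stage(
        "tree",
        tree_stage,
        skip_reason="" if len(taxa_present - {Taxon.UNKNOWN}) >= 2 else
        "at least two labelled taxa required",
    )
    run_stage(
        "classification",
        lambda: classify_cohort(cohort),
        skip_reason="" if any_cornuti else
        "decision rule needs CGPI; no cornuti measured",
    )
    return report


def render_report(
    report: PipelineReport, outdir: str | Path, format: str = "csv-bundle"
) -> list[Path]:
    """Write a report to disk as a text summary or a CSV bundle.

    ``csv-bundle`` writes one CSV per tabular section plus a manifest;
    ``text`` writes a single human-readable summary at 3-decimal precision.
    Returns the written paths.
    """
    if format not in {"text", "csv-bundle"}:
        raise ValueError(f"unknown format {format!r}; options: text, csv-bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if format == "csv-bundle":
        manifest = []
        for name, stage in report.stages.items():
            if stage.status != "ok":
                manifest.append(f"{name}: {stage.status} ({stage.reason})")
                continue
            payload = stage.payload
            items = (
                payload.items() if isinstance(payload, dict) else [(name, payload)]
            )
            for sub, obj in items:
                fname = f"{name}.csv" if sub == name else f"{name}_{sub}.csv"
                path = outdir / fname
                if isinstance(obj, pd.DataFrame):
                    obj.to_csv(path, index=False, lineterminator="\n")
                else:  # tree model
                    path = outdir / f"{name}.txt"
                    path.write_text(tree_to_text(obj))
                manifest.append(f"{name}: ok -> {path.name}")
                written.append(path)
        prov = outdir / "provenance.txt"
        prov.write_text(
            "".join(f"{k}={v}\n" for k, v in report.provenance.items())
            + "".join(line + "\n" for line in manifest)
        )
        written.append(prov)
        return written

    lines = ["dendromorph pipeline report", "=" * 27, ""]
    for k, v in report.provenance.items():
        lines.append(f"{k}: {v}")
    lines.append("")
    for name, stage in report.stages.items():
        lines.append(f"## {name} [{stage.status}]")
        if stage.status != "ok":
            lines.append(f"   reason: {stage.reason}")
            lines.append("")
            continue
        payload = stage.payload
        items = payload.items() if isinstance(payload, dict) else [(name, payload)]
        for sub, obj in items:
            if sub != name:
                lines.append(f"### {sub}")
            if isinstance(obj, pd.DataFrame):
                lines.append(obj.round(3).to_string(index=False))
            else:
                lines.append(tree_to_text(obj).rstrip())
            lines.append("")
    path = outdir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    written.append(path)
    return written
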