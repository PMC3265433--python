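"""End-to-end orchestration: curves -> pi-P8 -> group comparison, and
preset -> customized zone stiffness.

``run_comparison`` reproduces the experimental analysis: normalize every
marker curve, extract the pi-P8 deviation, average repeated trials per
subject and surface, and compare the surface groups with classical and
Welch ANOVA, Levene's test and Tamhane's T2 post hoc. ``run_customization``
reproduces the modeling analysis: build a preset body, optimize the zoned
mattress stiffness, and report the achieved deviation against soft and firm
uniform baselines.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__ as _version
from .body_bed_model import (PRESETS, AnthropometricPreset,
                             MattressArrangement, build_body, optimize_zones,
                             solve_equilibrium)
from .config import config_hash, default_config
from .group_stats import (DegenerateVarianceError, GroupComparison,
                          GroupSample, compare_groups)
from .mattress_metrics import StiffnessTable
from .spine_geometry import (SpinalCurve, SpineGeometryError, compute_p8,
                             normalize_curve, read_marker_csv)
from .synthetic_data import Cohort

__all__ = ["RunReport", "CustomizationReport", "PipelineError",
           "run_comparison", "run_customization",
           "report_to_json", "report_from_json"]

logger = logging.getLogger("spinealign")

REPORT_SCHEMA_VERSION = 1


class PipelineError(ValueError):
    """Pipeline-level input problem."""


@dataclass(frozen=True)
class RunReport:
    """Serializable record of a surface-comparison run."""

    schema_version: int
    per_subject: pd.DataFrame          # subject, surface, dev_deg (averaged)
    group_summary: pd.DataFrame        # surface, n, mean, sd
    comparison: GroupComparison | None
    degenerate: bool
    skipped: tuple[str, ...]
    provenance: dict[str, Any]


@dataclass(frozen=True)
class CustomizationReport:
    """Zone customization outcome for one anthropometric preset."""

    preset: str
    table: StiffnessTable
    achieved_dev_deg: float
    soft_dev_deg: float
    firm_dev_deg: float
    provenance: dict[str, Any]


def _dev_from_curve(curve: SpinalCurve) -> float:
    if curve.frame == "raw":
        curve = normalize_curve(curve)
    return compute_p8(curve).dev_deg


def _load_inputs(inputs: str | Path | Cohort | Sequence,
                 ) -> tuple[pd.DataFrame, list[str]]:
    """Collect (subject, surface, repeat, dev_deg) rows; returns skipped ids."""
    rows, skipped = [], []
    if isinstance(inputs, Cohort):
        for r in inputs.records:
            rows.append({"subject": r.subject, "surface": r.surface,
                         "repeat": r.repeat, "dev_deg": _dev_from_curve(r.curve)})
        return pd.DataFrame(rows), skipped
    path = Path(inputs)
    index = path / "index.csv"
    if not index.exists():
        raise PipelineError(f"no index.csv in cohort directory {path}")
    idx = pd.read_csv(index)
    for rec in idx.itertuples():
        try:
            curve = read_marker_csv(path / rec.path)
            dev = _dev_from_curve(curve)
        except (SpineGeometryError, OSError, ValueError) as exc:
            logger.warning("skipping %s: %s", rec.path, exc)
            skipped.append(str(rec.path))
            continue
        rows.append({"subject": rec.subject, "surface": rec.surface,
                     "repeat": getattr(rec, "repeat", 1), "dev_deg": dev})
    return pd.DataFrame(rows), skipped


def run_comparison(inputs: str | Path | Cohort,
                   config: Mapping | None = None,
                   seed: int | None = None) -> RunReport:
    """Compare pi-P8 deviations across sleep surfaces.

    ``inputs`` is either an in-memory :class:`~spinealign.synthetic_data.Cohort`
    or a cohort directory with ``index.csv`` (columns subject, surface,
    repeat, path) and marker CSVs. Repeated trials are averaged per subject
    and surface before testing. Unparseable curves are skipped with a logged
    warning; if any group's within variance collapses, the statistical tests
    are reported as degenerate rather than failing the run.
    """
    cfg = default_config() if config is None else dict(config)
    stats_cfg = cfg.get("stats", default_config()["stats"])
    table, skipped = _load_inputs(inputs)
    if table.empty:
        raise PipelineError("no usable curves in input")
    per_subject = (table.groupby(["subject", "surface"], as_index=False)
                   ["dev_deg"].mean())
    logger.info("curves in: %d, usable: %d, subjects x surfaces: %d",
                len(table) + len(skipped), len(table), len(per_subject))

    counts = per_subject.groupby("surface")["subject"].nunique()
    usable = counts[counts >= 2]
    if len(usable) < 2:
        raise PipelineError(
            f"need >= 2 surfaces with >= 2 subjects each, got {counts.to_dict()}")

    group_summary = (per_subject.groupby("surface")["dev_deg"]
                     .agg(n="count", mean="mean", sd="std").reset_index())
    groups = [GroupSample(surface, sub["dev_deg"].to_numpy())
              for surface, sub in per_subject.groupby("surface")
              if surface in usable.index]
    degenerate = False
    comparison: GroupComparison | None = None
    try:
        comparison = compare_groups(groups, alpha=float(stats_cfg["alpha"]),
                                    levene_center=str(stats_cfg["levene_center"]))
    except DegenerateVarianceError as exc:
        logger.warning("degenerate group variance: %s", exc)
        degenerate = True

    provenance = {"config_hash": config_hash(cfg), "seed": seed,
                  "spinealign_version": _version,
                  "schema_version": REPORT_SCHEMA_VERSION}
    return RunReport(schema_version=REPORT_SCHEMA_VERSION,
                     per_subject=per_subject, group_summary=group_summary,
                     comparison=comparison, degenerate=degenerate,
                     skipped=tuple(skipped), provenance=provenance)


def run_customization(preset: AnthropometricPreset | str,
                      config: Mapping | None = None) -> CustomizationReport:
    """Customize zone stiffness for a preset and report the improvement."""
    cfg = default_config() if config is None else dict(config)
    bed_cfg = cfg.get("bed", default_config()["bed"])
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise PipelineError(f"unknown preset {preset!r}")
        preset = PRESETS[preset]
    body = build_body(preset, cfg.get("body"))
    coupling = float(bed_cfg["coupling"])
    n_zones = int(bed_cfg["n_zones"])
    soft = MattressArrangement.tiling(
        body, [float(bed_cfg["soft_stiffness"])] * n_zones)
    firm = MattressArrangement.tiling(
        body, [float(bed_cfg["firm_stiffness"])] * n_zones)
    soft_dev = solve_equilibrium(body, soft, coupling).dev_deg
    firm_dev = solve_equilibrium(body, firm, coupling).dev_deg
    result = optimize_zones(body, bounds=tuple(bed_cfg["bounds"]),
                            coupling=coupling, tol=float(bed_cfg["tol_deg"]),
                            n_zones=n_zones,
                            max_sweeps=int(bed_cfg["max_sweeps"]))
    provenance = {"config_hash": config_hash(cfg),
                  "spinealign_version": _version}
    return CustomizationReport(preset=preset.name, table=result.table,
                               achieved_dev_deg=result.dev_deg,
                               soft_dev_deg=soft_dev, firm_dev_deg=firm_dev,
                               provenance=provenance)


# ---------------------------------------------------------------------------
# Lossless JSON serialization of reports.

def _comparison_to_dict(c: GroupComparison | None) -> dict | None:
    if c is None:
        return None
    d = dataclasses.asdict(c)
    d["pairwise"] = [dict(p, pair=list(p["pair"])) for p in d["pairwise"]]
    return d


def report_to_json(report: RunReport, path: str | Path | None = None) -> str:
    payload = {
        "schema_version": report.schema_version,
        "per_subject": report.per_subject.to_dict(orient="records"),
        "group_summary": report.group_summary.to_dict(orient="records"),
        "comparison": _comparison_to_dict(report.comparison),
        "degenerate": report.degenerate,
        "skipped": list(report.skipped),
        "provenance": report.provenance,
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def report_from_json(source: str | Path) -> RunReport:
    """Inverse of :func:`report_to_json` (accepts a path or a JSON string)."""
    text = (Path(source).read_text()
            if isinstance(source, Path) or (isinstance(source, str)
                                            and "\n" not in source
                                            and Path(source).exists())
            else str(source))
    payload = json.loads(text)
    comparison = None
    if payload["comparison"] is not None:
        from .group_stats import AnovaResult, PairwiseResult
        c = payload["comparison"]
        comparison = GroupComparison(
            classic=AnovaResult(**c["classic"]),
            welch=AnovaResult(**c["welch"]),
            levene=AnovaResult(**c["levene"]),
            pairwise=tuple(PairwiseResult(**dict(p, pair=tuple(p["pair"])))
                           for p in c["pairwise"]),
            alpha=c["alpha"],
        )
    return RunReport(
        schema_version=payload["schema_version"],
        per_subject=pd.DataFrame(payload["per_subject"]),
        group_summary=pd.DataFrame(payload["group_summary"]),
        comparison=comparison,
        degenerate=payload["degenerate"],
        skipped=tuple(payload["skipped"]),
        provenance=payload["provenance"],
    )
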