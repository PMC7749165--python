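"""Config-driven orchestration of the full crosslink/structure analysis.

A run config (YAML) names a reference structure with its subunit map, one
or more crosslink tables (one per crosslinked complex), region
definitions, a named-distance measurement panel, and SASA interface
settings. ``run_pipeline`` executes

    read -> FDR filter -> deduplicate -> map -> classify -> null ->
    region counts -> cross-complex comparison

plus the measurement panel and the interface decomposition, and writes
every result as a delimited table under the output directory together
with a run log recording thresholds, seeds and versions. All randomness
is seeded, so re-running an identical config reproduces the tables
byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .distance_analysis import (
    AnalysisConfig,
    RegionDef,
    compare_complexes,
    map_crosslinks,
    random_pair_null,
)
from .sasa import RadiiTable, interface_decomposition
from .structure_model import StructureModel, SubunitMap, read_structure
from .xlink_table import CrosslinkSet, deduplicate, filter_fdr, read_crosslink_table

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    reference_structure: Path
    subunit_map: Path
    output_dir: Path
    complexes: list[dict[str, Any]] = field(default_factory=list)
    regions: list[dict[str, Any]] = field(default_factory=list)
    measurements: list[dict[str, Any]] = field(default_factory=list)
    analysis: dict[str, Any] = field(default_factory=dict)
    sasa: dict[str, Any] = field(default_factory=dict)
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        labels = [c["label"] for c in self.complexes]
        if len(labels) != len(set(labels)):
            raise ValueError("complex labels must be unique")


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def _p(v: str) -> Path:
        p = Path(v)
        return p if p.is_absolute() else base / p

    try:
        return RunConfig(
            reference_structure=_p(raw["reference_structure"]),
            subunit_map=_p(raw["subunit_map"]),
            output_dir=_p(raw.get("output_dir", "xlstruct_out")),
            complexes=[
                {**c, "crosslinks": _p(c["crosslinks"])} for c in raw.get("complexes", [])
            ],
            regions=raw.get("regions", []),
            measurements=raw.get("measurements", []),
            analysis=raw.get("analysis", {}),
            sasa=raw.get("sasa", {}),
            fdr_threshold=float(raw.get("fdr_threshold", 0.05)),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing config key {exc}") from exc


def _provenance_header(cfg: AnalysisConfig, extra: dict[str, Any]) -> str:
    fields = {
        "xlstruct": __version__,
        "distance_limit": cfg.distance_limit,
        "null_mode": cfg.null_mode,
        "seed": cfg.seed,
        **extra,
    }
    return "# " + " ".join(f"{k}={v}" for k, v in fields.items()) + "\n"


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; return the paths of the written tables."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    try:
        model = read_structure(config.reference_structure)
        submap = SubunitMap.from_file(config.subunit_map)
        submap.validate(model)
    except Exception as exc:
        raise PipelineError("read-structure", str(exc)) from exc

    acfg = AnalysisConfig(**config.analysis)
    regions = [
        RegionDef(
            label=r["label"],
            role=r["role"],
            ranges=tuple(tuple(x) for x in r["ranges"]),
        )
        for r in config.regions
    ]

    sets: list[CrosslinkSet] = []
    for entry in config.complexes:
        label = entry["label"]
        try:
            xset = read_crosslink_table(
                entry["crosslinks"],
                entry.get("column_map"),
                complex_label=label,
            )
            xset = filter_fdr(xset, config.fdr_threshold)
            xset = deduplicate(xset)
        except Exception as exc:
            raise PipelineError("read-crosslinks", f"{label}: {exc}") from exc
        sets.append(xset)

        mapped = map_crosslinks(xset, model, submap, acfg)
        rows = [
            {
                "protein_a": m.link.protein_a,
                "resnum_a": m.link.resnum_a,
                "protein_b": m.link.protein_b,
                "resnum_b": m.link.resnum_b,
                "chain_a": m.chain_a or "",
                "chain_b": m.chain_b or "",
                "distance": "" if m.distance is None else round(m.distance, 3),
                "class": m.klass,
                "reason": m.reason,
            }
            for m in mapped
        ]
        p = out / f"mapped_{label}.tsv"
        _write_table(
            pd.DataFrame(rows), p, _provenance_header(acfg, {"complex": label})
        )
        written[f"mapped_{label}"] = p

    if sets:
        try:
            comparison = compare_complexes(sets, model, submap, regions, acfg)
        except Exception as exc:
            raise PipelineError("compare-complexes", str(exc)) from exc
        p = out / "comparison.tsv"
        _write_table(
            comparison.table, p, _provenance_header(acfg, {"fdr": config.fdr_threshold})
        )
        written["comparison"] = p

    try:
        null = random_pair_null(model, submap, acfg)
    except Exception as exc:
        raise PipelineError("null-distribution", str(exc)) from exc
    p = out / "null_distances.tsv"
    with open(p, "w") as fh:
        fh.write(_provenance_header(acfg, {"n_pairs": null.n_pairs, "mode": null.mode}))
        fh.write("distance\n")
        for d in null.distances:
            fh.write(f"{d:.4f}\n")
    written["null"] = p

    if config.measurements:
        from .geometry import named_distance

        rows = []
        for m in config.measurements:
            site_a = tuple(m["site_a"])
            site_b = tuple(m["site_b"])
            try:
                d, combos = named_distance(model, submap, site_a, site_b, return_all=True)
            except KeyError as exc:
                raise PipelineError("measure", f"{m['label']}: {exc}") from exc
            rows.append(
                {
                    "label": m["label"],
                    "site_a": ":".join(str(x) for x in site_a),
                    "site_b": ":".join(str(x) for x in site_b),
                    "distance": round(d, 3),
                    "n_combinations": len(combos),
                }
            )
        p = out / "measurements.tsv"
        _write_table(pd.DataFrame(rows), p, _provenance_header(acfg, {}))
        written["measurements"] = p

    if config.sasa:
        scfg = config.sasa
        radii = (
            RadiiTable.from_file(scfg["radii_table"])
            if "radii_table" in scfg
            else RadiiTable(probe_radius=float(scfg.get("probe_radius", 1.4)))
        )
        n_points = int(scfg.get("n_points", 960))
        try:
            reports, combined, discrepancy = interface_decomposition(
                model,
                submap,
                scfg["probe_group"],
                scfg["partners"],
                radii,
                n_points,
            )
        except Exception as exc:
            raise PipelineError("sasa-interface", str(exc)) from exc
        rows = [
            {
                "partner": r.partner,
                "buried_total": round(r.buried_total, 2),
                "buried_on_partner": round(r.buried_on_partner, 2),
                "buried_on_probe_group": round(r.buried_on_probe_group, 2),
            }
            for r in reports
        ]
        rows.append(
            {
                "partner": "ALL",
                "buried_total": round(combined.buried_total, 2),
                "buried_on_partner": round(combined.buried_on_partner, 2),
                "buried_on_probe_group": round(combined.buried_on_probe_group, 2),
            }
        )
        p = out / "interface.tsv"
        _write_table(
            pd.DataFrame(rows),
            p,
            _provenance_header(
                acfg,
                {
                    "probe": radii.probe_radius,
                    "n_points": n_points,
                    "three_body_discrepancy": round(discrepancy, 2),
                },
            ),
        )
        written["interface"] = p

    log_path = out / "run.log"
    with open(log_path, "w") as fh:
        fh.write(f"xlstruct {__version__}\n")
        fh.write(f"reference_structure={config.reference_structure}\n")
        fh.write(f"fdr_threshold={config.fdr_threshold}\n")
        fh.write(f"distance_limit={acfg.distance_limit}\n")
        fh.write(f"null_mode={acfg.null_mode} seed={acfg.seed}\n")
        fh.write(f"complexes={[c['label'] for c in config.complexes]}\n")
        fh.write(f"tables={sorted(str(v.name) for v in written.values())}\n")
    written["log"] = log_path
    return written
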