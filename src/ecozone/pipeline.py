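"""End-to-end zoning pipeline: classify → group overlay → score → zone.

The pipeline can run fully in memory on a :class:`StudyAreaBundle`
(tests, acceptance) or from a YAML configuration referencing rasters,
GeoJSON feature files and AHP matrix CSVs on disk (CLI). Every stage
records what it did — breaks, weights, consistency ratios, the seed — in
a run report so a real-data run is auditable and reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .ahp import AHPResult, load_matrix_csv, weights_from_matrix
from .factors import (
    FactorSpec,
    classify_aspect,
    classify_categorical,
    classify_continuous,
    classify_distance,
    classify_range,
    reference_factors,
)
from .grid import FeatureSet, GridLayer, GridSpec, euclidean_distance, load_features, load_grid, save_grid
from .hakanson import HakansonConstants, risk_grid
from .synthetic import StudyAreaBundle
from .zoning import (
    ScenarioSpec,
    ZoneStats,
    apply_scenario,
    combine_scores,
    comprehensive_group_map,
    weighted_overlay,
    zone_statistics,
)

__all__ = ["PipelineResult", "classify_all_factors", "run_pipeline", "run_pipeline_from_config"]

log = logging.getLogger(__name__)

GROUP_ORDER = ("topographic", "ecological", "human")


@dataclass
class PipelineResult:
    level_maps: dict[str, GridLayer]
    group_overlays: dict[str, GridLayer]
    group_maps: dict[str, GridLayer]
    scores: GridLayer
    zones: GridLayer
    stats: ZoneStats
    report: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, layer in self.level_maps.items():
            save_grid(layer, outdir / f"level_{name}.asc")
        for group in self.group_maps:
            save_grid(self.group_overlays[group], outdir / f"overlay_{group}.asc")
            save_grid(self.group_maps[group], outdir / f"group_{group}.asc")
        save_grid(self.scores, outdir / "scores.asc")
        save_grid(self.zones, outdir / "zones.asc")
        self.stats.to_frame().to_csv(outdir / "zone_stats.csv", index=False)
        (outdir / "zone_legend.csv").write_text(
            "code,zone\n1,NMCA\n2,SMCA\n3,FMCA\n"
        )
        (outdir / "run_report.yaml").write_text(yaml.safe_dump(self.report, sort_keys=False))


def _classify_one(
    fspec: FactorSpec,
    layers: dict[str, GridLayer],
    features: dict[str, FeatureSet],
    spec: GridSpec,
    seed: int | None,
) -> GridLayer:
    p = fspec.params
    try:
        if fspec.classifier == "continuous_jenks":
            return classify_continuous(
                layers[fspec.name], k=5, ascending=bool(p.get("ascending", True)), seed=seed
            )
        if fspec.classifier == "aspect":
            return classify_aspect(layers[fspec.name])
        if fspec.classifier == "distance":
            dist = euclidean_distance(features[fspec.name], spec)
            return classify_distance(
                dist, p["thresholds"], near_is_sensitive=bool(p.get("near_is_sensitive", True))
            )
        if fspec.classifier == "categorical":
            mapping = {int(k): int(v) for k, v in p["mapping"].items()}
            return classify_categorical(layers[fspec.name], mapping)
        if fspec.classifier == "range":
            intervals = [tuple(iv) for iv in p["intervals"]]
            return classify_range(layers[fspec.name], intervals)
        if fspec.classifier == "heavy_metal_ri":
            constants = HakansonConstants()
            metals = {
                m: layers[f"metal_{m}"] for m in constants.background
                if f"metal_{m}" in layers
            }
            ri = risk_grid(metals, constants)
            return classify_continuous(ri, k=5, ascending=True, seed=seed)
        raise ValueError(f"unknown classifier {fspec.classifier!r}")
    except Exception as exc:  # annotate which stage/factor failed
        raise RuntimeError(f"classification failed for factor {fspec.name!r}: {exc}") from exc


def classify_all_factors(
    factors: list[FactorSpec],
    layers: dict[str, GridLayer],
    features: dict[str, FeatureSet],
    spec: GridSpec,
    seed: int | None = None,
) -> dict[str, GridLayer]:
    return {f.name: _classify_one(f, layers, features, spec, seed) for f in factors}


def _resolve_weights(
    factors: list[FactorSpec],
    weights_by_group: dict[str, dict[str, float]] | None,
    matrices: dict[str, tuple[np.ndarray, tuple[str, ...]]] | None,
    report: dict,
) -> dict[str, dict[str, float]]:
    """Per-group factor weight dicts, from explicit weights or AHP matrices."""
    if weights_by_group is not None:
        out = {g: dict(w) for g, w in weights_by_group.items()}
    elif matrices is not None:
        out = {}
        for group, (m, names) in matrices.items():
            res: AHPResult = weights_from_matrix(m, names)
            report.setdefault("ahp", {})[group] = {
                "lambda_max": float(res.lambda_max),
                "ci": float(res.ci),
                "cr": float(res.cr),
                "weights": {n: float(w) for n, w in zip(names, res.weights)},
            }
            out[group] = dict(zip(names, (float(w) for w in res.weights)))
    else:
        # equal weights within each group
        out = {}
        for f in factors:
            out.setdefault(f.group, {})[f.name] = 1.0
        out = {g: {n: 1.0 / len(w) for n in w} for g, w in out.items()}

    for f in factors:
        if f.name not in out.get(f.group, {}):
            raise ValueError(f"no weight for factor {f.name!r} in group {f.group!r}")
    for group, w in out.items():
        s = sum(w.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"group {group!r} weights sum to {s}, expected 1")
    return out


def run_pipeline(
    bundle: StudyAreaBundle,
    *,
    factors: list[FactorSpec] | None = None,
    weights_by_group: dict[str, dict[str, float]] | None = None,
    matrices: dict[str, tuple[np.ndarray, tuple[str, ...]]] | None = None,
    scenario: str | ScenarioSpec = "balanced",
    seed: int | None = None,
) -> PipelineResult:
    """Run classify → overlay → comprehensive maps → scores → zones → stats."""
    factors = factors or reference_factors()
    report: dict = {"seed": seed, "scenario": scenario if isinstance(scenario, str) else scenario.name}
    weights = _resolve_weights(factors, weights_by_group, matrices, report)
    report["weights"] = {g: dict(w) for g, w in weights.items()}

    level_maps = classify_all_factors(factors, bundle.layers, bundle.features, bundle.spec, seed)

    group_overlays: dict[str, GridLayer] = {}
    group_maps: dict[str, GridLayer] = {}
    for group in GROUP_ORDER:
        members = [f.name for f in factors if f.group == group]
        if not members:
            raise ValueError(f"group {group!r} has no factors")
        maps = [level_maps[n] for n in members]
        w = [weights[group][n] for n in members]
        overlay = weighted_overlay(maps, w)
        group_overlays[group] = overlay
        group_maps[group] = comprehensive_group_map(overlay, seed=seed)

    scores = combine_scores(*(group_maps[g] for g in GROUP_ORDER))
    zones = apply_scenario(scores, scenario)
    stats = zone_statistics(zones)

    report["zone_stats"] = {
        z: {"cells": stats.counts[z], "area_km2": stats.area_km2[z], "proportion": stats.proportion[z]}
        for z in stats.counts
    }
    report["level_histograms"] = {
        name: {int(c): int(n) for c, n in zip(*np.unique(lm.valid_values(), return_counts=True))}
        for name, lm in level_maps.items()
    }
    return PipelineResult(level_maps, group_overlays, group_maps, scores, zones, stats, report)


# ---------------------------------------------------------------------------
# Config-file front end
# ---------------------------------------------------------------------------

def load_bundle_from_config(cfg_path: str | Path) -> tuple[StudyAreaBundle, dict]:
    """Read the YAML pipeline config plus the rasters/features it names."""
    cfg_path = Path(cfg_path)
    cfg = yaml.safe_load(cfg_path.read_text())
    base = cfg_path.parent
    g = cfg["grid"]
    spec = GridSpec(
        int(g["n_rows"]), int(g["n_cols"]), float(g["cell_size"]),
        float(g.get("origin_x", 0.0)), float(g.get("origin_y", 0.0)),
        str(g.get("crs_id", "EPSG:32650")),
    )
    factors = [
        FactorSpec(f["name"], f["group"], f["classifier"], dict(f.get("params") or {}))
        for f in cfg["factors"]
    ]
    layers: dict[str, GridLayer] = {}
    features: dict[str, FeatureSet] = {}
    for f in factors:
        if f.classifier == "distance":
            features[f.name] = load_features(base / f"{f.name}.geojson")
        elif f.classifier == "heavy_metal_ri":
            for metal in HakansonConstants().background:
                layers[f"metal_{metal}"] = load_grid(base / f"metal_{metal}.asc", spec)
        else:
            layers[f.name] = load_grid(base / f"{f.name}.asc", spec)

    from .synthetic import SyntheticConfig  # placeholder config for provenance

    bundle = StudyAreaBundle(spec, layers, features, SyntheticConfig(seed=int(cfg.get("seed", 0))))
    return bundle, cfg


def run_pipeline_from_config(cfg_path: str | Path, outdir: str | Path | None = None) -> PipelineResult:
    bundle, cfg = load_bundle_from_config(cfg_path)
    base = Path(cfg_path).parent
    factors = [
        FactorSpec(f["name"], f["group"], f["classifier"], dict(f.get("params") or {}))
        for f in cfg["factors"]
    ]
    matrices = None
    if "ahp_matrices" in cfg:
        matrices = {
            group: load_matrix_csv(base / path)
            for group, path in cfg["ahp_matrices"].items()
        }
    result = run_pipeline(
        bundle,
        factors=factors,
        matrices=matrices,
        weights_by_group=cfg.get("weights"),
        scenario=cfg.get("scenario", "balanced"),
        seed=cfg.get("seed"),
    )
    if outdir is not None:
        result.write(outdir)
    return result
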