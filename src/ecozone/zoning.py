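"""Weighted group overlay, score summation and multi-scenario zoning.

The zoning core works in three stages:

1. Within each factor group, the five-level sensitivity rasters are
   combined by a weighted overlay (cell-wise Σ wᵢ·codeᵢ with weights from
   the group's pairwise-comparison matrix), and the continuous overlay is
   cut by natural breaks into a three-class *group comprehensive map*
   valued 3 (highly), 2 (moderately), 1 (non-sensitive).
2. The three group maps are summed cell-wise, giving an integer score
   grid on 3..9.
3. A *scenario* — a total, monotone mapping from scores to control
   zones — turns the score grid into first-level (FMCA), second-level
   (SMCA) and non-management (NMCA) control areas. Three policy scenarios
   are built in; custom ones are validated for monotonicity.

Zone raster codes: 3 = FMCA, 2 = SMCA, 1 = NMCA.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridLayer
from .jenks import compute_breaks, classify_with_breaks

__all__ = [
    "FMCA",
    "SMCA",
    "NMCA",
    "SCENARIOS",
    "ScenarioSpec",
    "ZoneStats",
    "weighted_overlay",
    "comprehensive_group_map",
    "combine_scores",
    "apply_scenario",
    "enumerate_combinations",
    "zone_statistics",
    "compare_zone_stats",
]

FMCA, SMCA, NMCA = "FMCA", "SMCA", "NMCA"
ZONE_CODE = {NMCA: 1, SMCA: 2, FMCA: 3}
ZONE_OF_CODE = {v: k for k, v in ZONE_CODE.items()}


@dataclass(frozen=True)
class ScenarioSpec:
    """Total mapping from summed scores 3..9 to the three control zones."""

    name: str
    zone_of_score: Mapping[int, str]

    def __post_init__(self) -> None:
        scores = set(self.zone_of_score)
        if scores != set(range(3, 10)):
            raise ValueError("scenario must map every score 3..9")
        # monotone: zone protection level never drops as the score rises
        codes = [ZONE_CODE[self.zone_of_score[s]] for s in range(3, 10)]
        if any(b < a for a, b in zip(codes, codes[1:])):
            raise ValueError(f"scenario {self.name!r} interleaves zones")

    def scores_of(self, zone: str) -> set[int]:
        return {s for s, z in self.zone_of_score.items() if z == zone}


def _scenario(name: str, fmca: Sequence[int], smca: Sequence[int], nmca: Sequence[int]) -> ScenarioSpec:
    mapping = {s: FMCA for s in fmca}
    mapping |= {s: SMCA for s in smca}
    mapping |= {s: NMCA for s in nmca}
    return ScenarioSpec(name, mapping)


#: The three built-in policy scenarios.
SCENARIOS: dict[str, ScenarioSpec] = {
    "priority_ecological": _scenario("priority_ecological", (7, 8, 9), (5, 6), (3, 4)),
    "balanced": _scenario("balanced", (8, 9), (5, 6, 7), (3, 4)),
    "development": _scenario("development", (8, 9), (6, 7), (3, 4, 5)),
}


def weighted_overlay(level_maps: Sequence[GridLayer], weights: Sequence[float]) -> GridLayer:
    """Cell-wise Σ weightᵢ × levelᵢ over aligned sensitivity rasters.

    Weights must be positive and sum to 1 (within 1e-9). Output is nodata
    wherever any input is nodata.
    """
    if len(level_maps) != len(weights) or not level_maps:
        raise ValueError("need one weight per level map")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must be positive and sum to 1 (got sum={w.sum()!r})")
    first = level_maps[0]
    acc = np.zeros(first.values.shape, dtype=float)
    bad = np.zeros(first.values.shape, dtype=bool)
    for wi, layer in zip(w, level_maps):
        first.require_aligned(layer)
        bad |= layer.mask
        acc += wi * np.where(layer.mask, 0.0, layer.values.astype(float))
    out = np.where(bad, first.nodata, acc)
    return GridLayer(first.spec, out, nodata=first.nodata)


def comprehensive_group_map(overlay: GridLayer, seed: int | None = None) -> GridLayer:
    """Three-class natural-breaks cut of a group overlay, coded 1/2/3.

    3 = highly sensitive, 1 = non-sensitive. Degenerate (near-constant)
    overlays collapse to fewer classes with a warning.
    """
    valid = overlay.valid_values()
    if valid.size == 0:
        raise ValueError("overlay has no valid cells")
    if np.unique(valid).size == 1:
        warnings.warn("constant overlay: single-class group map", stacklevel=2)
        out = np.where(overlay.mask, int(overlay.nodata), 1)
        return overlay.with_values(out.astype(np.int64), nodata=int(overlay.nodata))
    breaks = compute_breaks(valid, 3, seed=seed)
    return classify_with_breaks(overlay, breaks, ascending=True)


def combine_scores(g1: GridLayer, g2: GridLayer, g3: GridLayer) -> GridLayer:
    """Sum three aligned 1/2/3 group maps into a 3..9 score grid."""
    groups = (g1, g2, g3)
    for g in groups[1:]:
        g1.require_aligned(g)
    bad = np.zeros(g1.values.shape, dtype=bool)
    total = np.zeros(g1.values.shape, dtype=np.int64)
    for g in groups:
        codes = g.values.astype(np.int64)
        ok = g.valid
        if not np.isin(codes[ok], (1, 2, 3)).all():
            raise ValueError("group maps must be coded 1/2/3")
        bad |= g.mask
        total += np.where(ok, codes, 0)
    out = np.where(bad, int(g1.nodata), total)
    return GridLayer(g1.spec, out, nodata=int(g1.nodata))


def apply_scenario(scores: GridLayer, scenario: ScenarioSpec | str) -> GridLayer:
    """Map a 3..9 score grid to zone codes 1/2/3 under a scenario."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    s = scores.values.astype(np.int64)
    ok = scores.valid
    if ok.any() and (s[ok].min() < 3 or s[ok].max() > 9):
        raise ValueError("scores must lie in 3..9")
    lut = np.zeros(10, dtype=np.int64)
    for score, zone in scenario.zone_of_score.items():
        lut[score] = ZONE_CODE[zone]
    out = np.where(ok, lut[np.clip(s, 0, 9)], int(scores.nodata))
    return scores.with_values(out, nodata=int(scores.nodata))


def enumerate_combinations() -> dict:
    """Enumerate the ordered group-map triples over {1,2,3}.

    Returns the total count (27), the count of triples per summed score
    3..9 (1, 3, 6, 7, 6, 3, 1), and for each built-in scenario the number
    of triples landing in each zone. The small NMCA share of the zoning —
    only 4 of 27 triples can sum to 3 or 4 — falls straight out of this
    table.
    """
    triples = list(itertools.product((1, 2, 3), repeat=3))
    per_sum: dict[int, int] = {s: 0 for s in range(3, 10)}
    for t in triples:
        per_sum[sum(t)] += 1
    per_scenario = {
        name: {
            zone: sum(per_sum[s] for s in spec.scores_of(zone))
            for zone in (FMCA, SMCA, NMCA)
        }
        for name, spec in SCENARIOS.items()
    }
    return {
        "total": len(triples),
        "per_sum": per_sum,
        "per_scenario": per_scenario,
        "triples": triples,
    }


@dataclass(frozen=True)
class ZoneStats:
    """Per-zone cell counts, areas (km²) and proportions of valid area."""

    counts: dict[str, int]
    area_km2: dict[str, float]
    proportion: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "zone": list(self.counts),
                "cells": list(self.counts.values()),
                "area_km2": [self.area_km2[z] for z in self.counts],
                "proportion": [self.proportion[z] for z in self.counts],
            }
        )


def zone_statistics(zones: GridLayer) -> ZoneStats:
    """Count cells per zone; area = cells × cell_size² / 10⁶ km²."""
    ok = zones.valid
    n_valid = int(ok.sum())
    if n_valid == 0:
        raise ValueError("zone map has no valid cells")
    cell_km2 = zones.spec.cell_area_km2
    counts, areas, props = {}, {}, {}
    for zone, code in ZONE_CODE.items():
        n = int((zones.values[ok] == code).sum())
        counts[zone] = n
        areas[zone] = n * cell_km2
        props[zone] = n / n_valid
    return ZoneStats(counts, areas, props)


def compare_zone_stats(a: ZoneStats, b: ZoneStats) -> dict[str, float]:
    """Percentage-point difference in zone proportions, a − b."""
    if set(a.proportion) != set(b.proportion):
        raise ValueError("zone vocabularies differ")
    return {z: 100.0 * (a.proportion[z] - b.proportion[z]) for z in a.proportion}
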