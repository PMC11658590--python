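"""Controlled comparison against the traditional single-overlay zoning.

The traditional workflow weights all factors at once, overlays them in a
single weighted sum, and cuts the result by natural breaks into three
control classes. To expose its sensitivity to expert judgment, panels of
experts each supply AHP weights; weights are averaged within each panel,
each panel's averaged weights drive one traditional zoning run, and the
resulting zone proportions are compared with each other and with the
grouped-overlay method's output. Large proportion swings between panels
with the same data demonstrate how strongly single-overlay zoning
inherits weighting subjectivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GridLayer
from .zoning import FMCA, NMCA, SMCA, ZONE_CODE, ZoneStats, compare_zone_stats, zone_statistics
from .jenks import compute_breaks, classify_with_breaks
from .zoning import weighted_overlay

__all__ = [
    "ExpertWeightTable",
    "average_expert_weights",
    "traditional_zoning",
    "compare_zonings",
    "load_expert_tables_csv",
]


@dataclass(frozen=True)
class ExpertWeightTable:
    """One expert's AHP weights for all factors, tagged with their groups.

    Within each group the weights must sum to 1 (each group was judged by
    its own pairwise matrix).
    """

    expert: str
    weights: dict[str, float]  # factor -> weight
    groups: dict[str, str]  # factor -> group

    def __post_init__(self) -> None:
        if set(self.weights) != set(self.groups):
            raise ValueError("weights and groups must cover the same factors")
        sums: dict[str, float] = {}
        for f, w in self.weights.items():
            if w <= 0:
                raise ValueError(f"non-positive weight for {f!r}")
            sums[self.groups[f]] = sums.get(self.groups[f], 0.0) + w
        for g, s in sums.items():
            if abs(s - 1.0) > 1e-6:
                raise ValueError(f"{self.expert}: group {g!r} weights sum to {s}")


def average_expert_weights(tables: list[ExpertWeightTable]) -> ExpertWeightTable:
    """Arithmetic mean of per-factor weights across a panel of experts.

    The mean of vectors that each sum to 1 within a group again sums to 1,
    so the result is a valid weight table.
    """
    if not tables:
        raise ValueError("need at least one expert table")
    ref = tables[0]
    for t in tables[1:]:
        if set(t.weights) != set(ref.weights) or t.groups != ref.groups:
            raise ValueError("expert tables must cover identical factor sets")
    mean = {
        f: float(np.mean([t.weights[f] for t in tables])) for f in ref.weights
    }
    return ExpertWeightTable("panel-mean", mean, dict(ref.groups))


def traditional_zoning(
    level_maps: dict[str, GridLayer],
    weights: ExpertWeightTable,
    *,
    group_shares: dict[str, float] | None = None,
    seed: int | None = None,
) -> GridLayer:
    """Single weighted overlay over ALL factors, then a 3-class cut.

    Each factor's global weight is its within-group weight times its
    group's share (groups equally weighted by default), so the global
    weights sum to 1. The overlay is classed by natural breaks into three
    zones: high → FMCA (3), middle → SMCA (2), low → NMCA (1).
    """
    if set(level_maps) != set(weights.weights):
        raise ValueError("level maps and weight table cover different factors")
    groups = sorted(set(weights.groups.values()))
    shares = group_shares or {g: 1.0 / len(groups) for g in groups}
    if abs(sum(shares.values()) - 1.0) > 1e-9:
        raise ValueError("group shares must sum to 1")

    names = list(level_maps)
    maps = [level_maps[n] for n in names]
    w = [weights.weights[n] * shares[weights.groups[n]] for n in names]
    overlay = weighted_overlay(maps, w)

    valid = overlay.valid_values()
    if np.unique(valid).size == 1:
        import warnings

        warnings.warn("constant overlay: single-zone traditional map", stacklevel=2)
        out = np.where(overlay.mask, int(overlay.nodata), ZONE_CODE[NMCA])
        return overlay.with_values(out.astype(np.int64), nodata=int(overlay.nodata))
    breaks = compute_breaks(valid, 3, seed=seed)
    return classify_with_breaks(overlay, breaks, ascending=True)


def compare_zonings(a: ZoneStats, b: ZoneStats) -> dict[str, float]:
    """Percentage-point proportion differences (a − b) per zone; sums to 0."""
    return compare_zone_stats(a, b)


def run_panel_experiment(
    level_maps: dict[str, GridLayer],
    panels: dict[str, list[ExpertWeightTable]],
    reference_stats: ZoneStats | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Average each panel's weights, zone, and tabulate zone proportions.

    Returns one row per panel (plus a ``reference`` row when supplied)
    with FMCA/SMCA/NMCA proportions — the layout used to argue about
    between-panel spread.
    """
    rows = []
    for name, tables in panels.items():
        mean = average_expert_weights(tables)
        zones = traditional_zoning(level_maps, mean, seed=seed)
        st = zone_statistics(zones)
        rows.append({"panel": name, **{z: st.proportion[z] for z in (FMCA, SMCA, NMCA)}})
    if reference_stats is not None:
        rows.append(
            {"panel": "reference", **{z: reference_stats.proportion[z] for z in (FMCA, SMCA, NMCA)}}
        )
    return pd.DataFrame(rows)


def load_expert_tables_csv(path: str | Path) -> list[ExpertWeightTable]:
    """Read (expert, factor, group, weight) rows into per-expert tables."""
    df = pd.read_csv(path)
    tables = []
    for expert, sub in df.groupby("expert", sort=True):
        weights = dict(zip(sub["factor"], sub["weight"].astype(float)))
        groups = dict(zip(sub["factor"], sub["group"]))
        tables.append(ExpertWeightTable(str(expert), weights, groups))
    return tables
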