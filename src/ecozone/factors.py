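"""Single-factor sensitivity classification.

Every raw factor input (terrain, vegetation, soils, proximity to
protected or disturbed features ...) is reduced to a five-level ordinal
sensitivity raster coded 1..5:

    1 non-sensitive, 2 slightly, 3 moderately, 4 highly, 5 extremely.

Continuous factors are classed by natural breaks; proximity factors by
fixed buffer distances; land use by a categorical lookup; soil pH by
explicit value ranges; slope aspect by 45° compass sectors. The reference
configuration carries 18 factors in three groups — six topographic, eight
ecological/environmental, four human-activity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid import FLAT_ASPECT, GridLayer
from .jenks import compute_breaks, classify_with_breaks

__all__ = [
    "LEVELS",
    "FactorSpec",
    "classify_continuous",
    "classify_distance",
    "classify_categorical",
    "classify_range",
    "classify_aspect",
    "reference_factors",
]

log = logging.getLogger(__name__)

#: code -> label for the five ordinal sensitivity levels
LEVELS = {
    1: "non-sensitive",
    2: "slightly sensitive",
    3: "moderately sensitive",
    4: "highly sensitive",
    5: "extremely sensitive",
}

GROUPS = ("topographic", "ecological", "human")


@dataclass(frozen=True)
class FactorSpec:
    """Binding of one factor to its group, classifier and parameters."""

    name: str
    group: str
    classifier: str  # continuous_jenks | distance | categorical | range | aspect | heavy_metal_ri
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def classify_continuous(
    layer: GridLayer, k: int = 5, ascending: bool = True, seed: int | None = None
) -> GridLayer:
    """Natural-breaks classification of a continuous raster into k levels."""
    valid = layer.valid_values()
    if valid.size == 0:
        raise ValueError("no valid cells to classify")
    if np.unique(valid).size == 1:
        warnings.warn("constant layer: single-class output", stacklevel=2)
        out = np.where(layer.mask, int(layer.nodata), 1)
        return layer.with_values(out.astype(np.int64), nodata=int(layer.nodata))
    breaks = compute_breaks(valid, k, seed=seed)
    return classify_with_breaks(layer, breaks, ascending=ascending)


def classify_distance(
    dist: GridLayer,
    thresholds: Sequence[float],
    near_is_sensitive: bool = True,
) -> GridLayer:
    """Buffer-distance classification: four increasing thresholds, metres.

    ``near_is_sensitive=True`` (rivers, reserves, heritage ...): d <= t1 is
    extremely sensitive (5), then 4, 3, 2, and beyond t4 non-sensitive (1).
    ``near_is_sensitive=False`` (roads): the coding is mirrored, so cells
    far from any road are the most sensitive. Thresholds are inclusive
    ("within 30 m" includes a cell exactly 30 m away).
    """
    t = list(thresholds)
    if len(t) != 4 or any(b <= a for a, b in zip(t, t[1:])):
        raise ValueError("need 4 strictly increasing distance thresholds")
    d = dist.values.astype(float)
    band = np.searchsorted(np.asarray(t, dtype=float), d, side="left")  # 0..4
    codes = 5 - band if near_is_sensitive else band + 1
    out = np.where(dist.mask, int(dist.nodata), codes)
    return dist.with_values(out.astype(np.int64), nodata=int(dist.nodata))


def classify_categorical(layer: GridLayer, mapping: dict[int, int]) -> GridLayer:
    """Lookup classification of a categorical raster (e.g. land use).

    Unmapped category codes become nodata with a logged warning.
    """
    if not mapping:
        raise ValueError("empty category mapping")
    vals = layer.values
    out = np.full(vals.shape, int(layer.nodata), dtype=np.int64)
    seen = set()
    for cat in np.unique(vals[layer.valid]):
        key = int(cat)
        if key in mapping:
            out[vals == cat] = int(mapping[key])
        else:
            seen.add(key)
    if seen:
        log.warning("unmapped land-use categories %s set to nodata", sorted(seen))
        warnings.warn(f"unmapped categories {sorted(seen)} set to nodata", stacklevel=2)
    return layer.with_values(out, nodata=int(layer.nodata))


def classify_range(
    layer: GridLayer, intervals: Sequence[tuple[float, float, int]]
) -> GridLayer:
    """Classification by explicit value intervals ``(lo, hi, level)``.

    Intervals are closed and must not overlap; values falling in a gap
    become nodata with a warning (e.g. a pH scheme that only names levels
    5, 3 and 1).
    """
    ints = sorted(intervals)
    for (lo1, hi1, _), (lo2, _hi2, _l) in zip(ints, ints[1:]):
        if lo2 < hi1:
            raise ValueError(f"overlapping intervals at {hi1} / {lo2}")
    vals = layer.values.astype(float)
    out = np.full(vals.shape, int(layer.nodata), dtype=np.int64)
    covered = layer.mask.copy()
    for lo, hi, level in ints:
        hit = (vals >= lo) & (vals <= hi) & layer.valid
        out[hit] = int(level)
        covered |= hit
    if not covered.all():
        warnings.warn(
            f"{int((~covered).sum())} cells fall outside all intervals; set to nodata",
            stacklevel=2,
        )
    return layer.with_values(out, nodata=int(layer.nodata))


#: compass sector center (deg) -> sensitivity level: south & southeast most
#: exposed, west & northwest least; flat cells have no insolation exposure.
ASPECT_LEVEL_OF_SECTOR = {0: 2, 45: 3, 90: 4, 135: 5, 180: 5, 225: 3, 270: 1, 315: 1}


def classify_aspect(aspect: GridLayer) -> GridLayer:
    """Classify slope aspect by eight 45° sectors centered on the compass points.

    S and SE face the strongest insolation → extremely sensitive (5);
    E → 4; NE and SW → 3; N → 2; W and NW → 1; flat (sentinel -1) → 1.
    """
    a = aspect.values.astype(float)
    flat = a == FLAT_ASPECT
    bad = aspect.valid & ~flat & ((a < 0) | (a >= 360))
    if bad.any():
        raise ValueError("aspect values must lie in [0, 360) or be the flat sentinel")
    sector = (np.round(a / 45.0).astype(int) % 8) * 45
    lut = np.zeros(360 // 45, dtype=np.int64)
    for center, level in ASPECT_LEVEL_OF_SECTOR.items():
        lut[center // 45] = level
    codes = lut[sector // 45]
    codes = np.where(flat, 1, codes)
    out = np.where(aspect.mask, int(aspect.nodata), codes)
    return aspect.with_values(out.astype(np.int64), nodata=int(aspect.nodata))


# ---------------------------------------------------------------------------
# Reference factor configuration: 18 factors in three groups (6 / 8 / 4)
# ---------------------------------------------------------------------------

#: land-use category codes used by the reference configuration
LANDUSE_CODES = {
    "woodland": 1,
    "cultivated": 2,
    "water": 3,
    "grassland": 4,
    "construction": 5,
}

LANDUSE_LEVELS = {1: 5, 2: 4, 3: 3, 4: 2, 5: 1}

PH_INTERVALS = [
    (0.0, 5.0, 5),  # strongly acid
    (5.0, 6.5, 3),
    (6.5, 7.5, 1),  # near-neutral
    (7.5, 8.5, 3),
    (8.5, 14.0, 5),  # strongly alkaline
]

WATER_BUFFERS = (30.0, 60.0, 90.0, 120.0)
PROTECTION_BUFFERS = (50.0, 100.0, 300.0, 600.0)
RESERVE_BUFFERS = (100.0, 500.0, 1000.0, 1500.0)
ROAD_BUFFERS = (50.0, 100.0, 150.0, 200.0)


def reference_factors() -> list[FactorSpec]:
    """The 18-factor reference configuration, grouped 6 / 8 / 4."""
    c = lambda name, group, **kw: FactorSpec(name, group, "continuous_jenks", dict(kw))
    d = lambda name, group, t, near=True: FactorSpec(
        name, group, "distance", {"thresholds": list(t), "near_is_sensitive": near}
    )
    return [
        # -- topographic and geomorphological (6)
        c("elevation", "topographic", ascending=True),
        c("slope", "topographic", ascending=True),
        FactorSpec("aspect", "topographic", "aspect"),
        c("relief", "topographic", ascending=True),
        d("water_areas", "topographic", WATER_BUFFERS),
        d("water_source_protection", "topographic", PROTECTION_BUFFERS),
        # -- ecological and environmental (8)
        c("ndvi", "ecological", ascending=True),
        FactorSpec("landuse", "ecological", "categorical", {"mapping": LANDUSE_LEVELS}),
        c("precipitation", "ecological", ascending=True),
        c("soil_erosion", "ecological", ascending=True),
        FactorSpec("heavy_metals", "ecological", "heavy_metal_ri"),
        FactorSpec("ph", "ecological", "range", {"intervals": PH_INTERVALS}),
        d("nature_reserves", "ecological", RESERVE_BUFFERS),
        d("scenic_areas", "ecological", RESERVE_BUFFERS),
        # -- human activity (4)
        d("roads", "human", ROAD_BUFFERS, near=False),
        # dark (low-light) areas are the undisturbed, sensitive ones
        c("nighttime_light", "human", ascending=False),
        d("cultural_heritage", "human", RESERVE_BUFFERS),
        d("coal_mines", "human", RESERVE_BUFFERS),
    ]
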