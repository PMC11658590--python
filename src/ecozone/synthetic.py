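"""Seeded synthetic study area: every factor input on one aligned grid.

The generator emulates the input inventory of a mountainous periurban
district — terrain, vegetation, precipitation, soils, protected areas,
infrastructure and mining legacy — at desk scale, so the whole pipeline
can run end-to-end with no external data. Continuous surfaces are
smoothed Gaussian random fields rescaled to realistic ranges; rivers and
roads are random polylines, protected areas are buffered random points,
heritage and coal sites are random point sets; heavy-metal concentration
fields are log-normal with medians at the regional background values, so
the synthetic integrated risk index centers near its background value of
53. Land use is a categorical field cut from a smooth surface at the
configured class mixture.

Everything is a pure function of the seed: the same config yields a
byte-identical bundle.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from shapely.geometry import LineString, Point

from .factors import reference_factors
from .grid import FeatureSet, GridLayer, GridSpec, save_features, save_grid, terrain_derivatives
from .hakanson import HakansonConstants

__all__ = ["SyntheticConfig", "StudyAreaBundle", "generate_study_area", "example_matrices"]


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 42
    n_rows: int = 120
    n_cols: int = 120
    cell_size: float = 30.0
    n_rivers: int = 3
    n_roads: int = 4
    n_reserves: int = 2
    n_scenic: int = 2
    n_protection_zones: int = 2
    n_heritage: int = 5
    n_coal_sites: int = 4
    metal_log_sigma: float = 0.4
    ndvi_range: tuple[float, float] = (-0.2, 0.9)
    ph_range: tuple[float, float] = (4.0, 9.5)
    elevation_range: tuple[float, float] = (100.0, 1500.0)
    precipitation_range: tuple[float, float] = (450.0, 700.0)
    erosion_range: tuple[float, float] = (0.0, 8.0)
    light_range: tuple[float, float] = (0.0, 63.0)
    #: woodland / cultivated / water / grassland / construction shares
    landuse_mixture: tuple[float, ...] = (0.84, 0.07, 0.003, 0.017, 0.07)
    smooth_sigma: float = 6.0

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if abs(sum(self.landuse_mixture) - 1.0) > 1e-6:
            raise ValueError("landuse mixture must sum to 1")

    @property
    def spec(self) -> GridSpec:
        return GridSpec(self.n_rows, self.n_cols, self.cell_size)


@dataclass
class StudyAreaBundle:
    """All 18 factor inputs: rasters, vector features, and the grid spec."""

    spec: GridSpec
    layers: dict[str, GridLayer]
    features: dict[str, FeatureSet]
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> Path:
        """Write rasters (.asc), features (.geojson), AHP matrices and a
        ready-to-run pipeline config; returns the config path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, layer in self.layers.items():
            save_grid(layer, outdir / f"{name}.asc")
        for name, feats in self.features.items():
            save_features(feats, outdir / f"{name}.geojson")
        matrices = example_matrices()
        _write_matrices(matrices, outdir)
        cfg = {
            "seed": self.config.seed,
            "scenario": "balanced",
            "grid": {
                "n_rows": self.spec.n_rows,
                "n_cols": self.spec.n_cols,
                "cell_size": self.spec.cell_size,
                "origin_x": self.spec.origin_x,
                "origin_y": self.spec.origin_y,
                "crs_id": self.spec.crs_id,
            },
            "ahp_matrices": {g: f"ahp_{g}.csv" for g in matrices},
            "factors": [
                {
                    "name": f.name,
                    "group": f.group,
                    "classifier": f.classifier,
                    "params": _plain(f.params),
                }
                for f in reference_factors()
            ],
        }
        cfg_path = outdir / "pipeline.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=False))
        return cfg_path


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardised smoothed Gaussian field (zero median, unit-ish spread)."""
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="reflect")
    f -= np.median(f)
    s = f.std()
    return f / s if s > 0 else f


def _scaled_field(rng, shape, sigma, lo, hi) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma, mode="reflect")
    fmin, fmax = f.min(), f.max()
    if fmax == fmin:
        return np.full(shape, (lo + hi) / 2.0)
    return lo + (f - fmin) / (fmax - fmin) * (hi - lo)


def _random_polyline(rng: np.random.Generator, spec: GridSpec) -> LineString:
    """A meandering line crossing the study area."""
    w = spec.n_cols * spec.cell_size
    h = spec.n_rows * spec.cell_size
    x0, y0 = spec.origin_x, spec.origin_y - h
    n_pts = 8
    horizontal = rng.random() < 0.5
    ts = np.linspace(0.0, 1.0, n_pts)
    drift = np.cumsum(rng.normal(0.0, 0.12, n_pts))
    off = rng.random() * 0.8 + 0.1 + drift - drift[0]
    off = np.clip(off, 0.02, 0.98)
    if horizontal:
        pts = [(x0 + t * w, y0 + o * h) for t, o in zip(ts, off)]
    else:
        pts = [(x0 + o * w, y0 + t * h) for t, o in zip(ts, off)]
    return LineString(pts)


def _random_polygon(rng: np.random.Generator, spec: GridSpec) -> "Point":
    w = spec.n_cols * spec.cell_size
    h = spec.n_rows * spec.cell_size
    cx = spec.origin_x + rng.random() * w
    cy = spec.origin_y - rng.random() * h
    radius = (0.05 + 0.10 * rng.random()) * min(w, h)
    return Point(cx, cy).buffer(radius, quad_segs=8)


def _random_points(rng: np.random.Generator, spec: GridSpec, n: int) -> list[Point]:
    w = spec.n_cols * spec.cell_size
    h = spec.n_rows * spec.cell_size
    return [
        Point(spec.origin_x + rng.random() * w, spec.origin_y - rng.random() * h)
        for _ in range(n)
    ]


def generate_study_area(cfg: SyntheticConfig | None = None) -> StudyAreaBundle:
    """Generate the full 18-factor synthetic bundle for ``cfg``."""
    cfg = cfg or SyntheticConfig()
    spec = cfg.spec
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.n_rows, cfg.n_cols)
    sig = cfg.smooth_sigma

    layers: dict[str, GridLayer] = {}
    mk = lambda arr: GridLayer(spec, arr)

    dem = mk(_scaled_field(rng, shape, sig, *cfg.elevation_range))
    layers["elevation"] = dem
    slope, aspect, relief = terrain_derivatives(dem)
    layers["slope"] = slope
    layers["aspect"] = aspect
    layers["relief"] = relief

    layers["ndvi"] = mk(_scaled_field(rng, shape, sig, *cfg.ndvi_range))
    layers["precipitation"] = mk(_scaled_field(rng, shape, sig, *cfg.precipitation_range))
    layers["soil_erosion"] = mk(_scaled_field(rng, shape, sig, *cfg.erosion_range))
    layers["nighttime_light"] = mk(_scaled_field(rng, shape, sig, *cfg.light_range))
    layers["ph"] = mk(_scaled_field(rng, shape, sig, *cfg.ph_range))

    # land use: cut a smooth surface at the configured class-share quantiles
    lu_field = _scaled_field(rng, shape, sig / 2, 0.0, 1.0)
    qs = np.cumsum(cfg.landuse_mixture)[:-1]
    cuts = np.quantile(lu_field, qs)
    lu = np.searchsorted(cuts, lu_field, side="right") + 1  # codes 1..5
    layers["landuse"] = GridLayer(spec, lu.astype(np.int64))

    # heavy metals: log-normal about the regional background medians
    constants = HakansonConstants()
    for metal, bg in constants.background.items():
        f = _smooth_field(rng, shape, sig) if cfg.metal_log_sigma > 0 else np.zeros(shape)
        conc = bg * np.exp(cfg.metal_log_sigma * f)
        layers[f"metal_{metal}"] = mk(conc)

    features = {
        "water_areas": FeatureSet(
            [_random_polyline(rng, spec) for _ in range(cfg.n_rivers)], "line"
        ),
        "water_source_protection": FeatureSet(
            [_random_polygon(rng, spec) for _ in range(cfg.n_protection_zones)], "polygon"
        ),
        "nature_reserves": FeatureSet(
            [_random_polygon(rng, spec) for _ in range(cfg.n_reserves)], "polygon"
        ),
        "scenic_areas": FeatureSet(
            [_random_polygon(rng, spec) for _ in range(cfg.n_scenic)], "polygon"
        ),
        "roads": FeatureSet(
            [_random_polyline(rng, spec) for _ in range(cfg.n_roads)], "line"
        ),
        "cultural_heritage": FeatureSet(_random_points(rng, spec, cfg.n_heritage), "point"),
        "coal_mines": FeatureSet(_random_points(rng, spec, cfg.n_coal_sites), "point"),
    }
    return StudyAreaBundle(spec, layers, features, cfg)


# ---------------------------------------------------------------------------
# Illustrative pairwise matrices (synthetic; NOT survey data)
# ---------------------------------------------------------------------------

_SAATY = np.array([1 / 9, 1 / 8, 1 / 7, 1 / 6, 1 / 5, 1 / 4, 1 / 3, 1 / 2,
                   1, 2, 3, 4, 5, 6, 7, 8, 9])

#: plausible within-group priority orderings used to build the example
#: matrices (synthetic stand-ins for expert judgment; not survey results)
_EXAMPLE_PRIORITIES = {
    "topographic": {
        "elevation": 3.0, "slope": 4.0, "aspect": 1.0, "relief": 2.0,
        "water_areas": 5.0, "water_source_protection": 4.0,
    },
    "ecological": {
        "ndvi": 5.0, "landuse": 4.0, "precipitation": 2.0, "soil_erosion": 3.0,
        "heavy_metals": 3.0, "ph": 1.0, "nature_reserves": 5.0, "scenic_areas": 2.0,
    },
    "human": {
        "roads": 2.0, "nighttime_light": 3.0, "cultural_heritage": 1.0,
        "coal_mines": 4.0,
    },
}


def example_matrices() -> dict[str, tuple[np.ndarray, tuple[str, ...]]]:
    """Near-consistent pairwise matrices from the illustrative priorities.

    Ratios are rounded to the nearest Saaty scale value, which keeps the
    matrices reciprocal and their consistency ratios small but non-zero —
    the texture of a real expert matrix.
    """
    out = {}
    for group, prio in _EXAMPLE_PRIORITIES.items():
        names = tuple(prio)
        v = np.array([prio[n] for n in names])
        n = len(v)
        m = np.ones((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ratio = v[i] / v[j]
                snapped = _SAATY[np.argmin(np.abs(_SAATY - ratio))]
                m[i, j] = snapped
                m[j, i] = 1.0 / snapped
        out[group] = (m, names)
    return out


def _write_matrices(matrices, outdir: Path) -> dict[str, Path]:
    import pandas as pd

    paths = {}
    for group, (m, names) in matrices.items():
        p = outdir / f"ahp_{group}.csv"
        pd.DataFrame(m, index=list(names), columns=list(names)).to_csv(p)
        paths[group] = p
    return paths
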