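"""Aligned single-band rasters and the generic grid operators built on them.

All spatial analysis in this package happens on a stack of rasters sharing
one :class:`GridSpec` — same shape, cell size, origin and projected CRS.
Alignment is *checked*, never repaired: resampling mismatched inputs is the
user's responsibility, because silently snapping grids together is the
classic source of off-by-one-cell zoning errors.

Rasters are stored on disk as ESRI ASCII grids (plain text, one header and
one row of numbers per grid row), with the CRS identifier in a ``.prj``
sidecar. Vector sources (rivers, roads, reserves, heritage sites ...) are
GeoJSON read into shapely geometries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import shape as geojson_shape
from shapely.geometry import mapping as geojson_mapping

__all__ = [
    "GridSpec",
    "GridLayer",
    "FeatureSet",
    "AlignmentError",
    "load_grid",
    "save_grid",
    "load_features",
    "save_features",
    "euclidean_distance",
    "terrain_derivatives",
    "FLAT_ASPECT",
]

#: Sentinel aspect value for cells with zero gradient (no defined azimuth).
FLAT_ASPECT = -1.0

DEFAULT_NODATA = -9999.0

# EPSG codes of common geographic (degree-unit) CRSs. Distances here are in
# metres, so degree grids are rejected instead of silently mis-measured.
_GEOGRAPHIC_EPSG = {"4326", "4258", "4269", "4490", "4610", "4214"}


class AlignmentError(ValueError):
    """Raised when rasters that must share one GridSpec do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of an aligned raster: shape, cell size and placement.

    ``origin_x``/``origin_y`` are the projected coordinates of the *top-left
    corner* of the top-left cell; row 0 is the northernmost row.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_id: str = "EPSG:32650"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive (metres)")
        code = self.crs_id.upper().replace("EPSG:", "")
        if code in _GEOGRAPHIC_EPSG:
            raise ValueError(
                f"{self.crs_id} is a geographic (degree) CRS; "
                "distances require a projected CRS in metres"
            )

    def aligned_with(self, other: "GridSpec") -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin_x, other.origin_x)
            and math.isclose(self.origin_y, other.origin_y)
            and self.crs_id == other.crs_id
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center as 2-D arrays."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6


@dataclass
class GridLayer:
    """A single-band raster: a GridSpec plus a 2-D value array.

    Cells equal to ``nodata`` are excluded from every statistic,
    classification, overlay and area sum downstream.
    """

    spec: GridSpec
    values: np.ndarray
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match spec "
                f"({self.spec.n_rows}, {self.spec.n_cols})"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return self.values == self.nodata

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "GridLayer":
        return GridLayer(self.spec, values, self.nodata if nodata is None else nodata)

    def require_aligned(self, other: "GridLayer") -> None:
        if not self.spec.aligned_with(other.spec):
            raise AlignmentError(f"grid specs differ: {self.spec} vs {other.spec}")


@dataclass
class FeatureSet:
    """Vector features (points, lines or polygons) in the layer CRS."""

    geometries: list
    kind: str  # "point" | "line" | "polygon"

    def __post_init__(self) -> None:
        if self.kind not in {"point", "line", "polygon"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid + .prj sidecar)
# ---------------------------------------------------------------------------

def _prj_path(path: Path) -> Path:
    return path.with_suffix(".prj")


def save_grid(layer: GridLayer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid; integers are written exactly."""
    path = Path(path)
    spec = layer.spec
    vals = np.asarray(layer.values)
    integral = np.issubdtype(vals.dtype, np.integer) or np.all(
        vals[layer.valid] == np.floor(vals[layer.valid])
    )
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x!r}\n"
        f"yllcorner {spec.origin_y - spec.n_rows * spec.cell_size!r}\n"
        f"cellsize {spec.cell_size!r}\n"
        f"NODATA_value {layer.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in vals:
            if integral:
                fh.write(" ".join(str(int(v)) for v in row))
            else:
                fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    _prj_path(path).write_text(spec.crs_id + "\n")


def load_grid(path: str | Path, expected_spec: GridSpec | None = None) -> GridLayer:
    """Read an ESRI ASCII grid; raises AlignmentError on spec mismatch."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header: dict[str, float] = {}
        while len(header) < 6:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated ASCII grid header")
            key, value = line.split()
            header[key.lower()] = float(value)
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    cell = header["cellsize"]
    prj = _prj_path(path)
    crs_id = prj.read_text().strip() if prj.exists() else GridSpec.crs_id
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
        crs_id=crs_id,
    )
    if expected_spec is not None and not spec.aligned_with(expected_spec):
        raise AlignmentError(
            f"{path}: grid spec {spec} not aligned with expected {expected_spec}"
        )
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} != header")
    return GridLayer(spec, values, nodata=header["nodata_value"])


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

_KIND_OF_GEOM = {
    "Point": "point",
    "MultiPoint": "point",
    "LineString": "line",
    "MultiLineString": "line",
    "Polygon": "polygon",
    "MultiPolygon": "polygon",
}


def load_features(path: str | Path) -> FeatureSet:
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    geoms = [geojson_shape(f["geometry"]) for f in feats]
    if not geoms:
        raise ValueError(f"{path}: empty feature collection")
    kinds = {_KIND_OF_GEOM[g.geom_type] for g in geoms}
    if len(kinds) != 1:
        raise ValueError(f"{path}: mixed geometry kinds {kinds}")
    return FeatureSet(geoms, kinds.pop())


def save_features(features: FeatureSet, path: str | Path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "properties": {}, "geometry": geojson_mapping(g)}
            for g in features.geometries
        ],
    }
    Path(path).write_text(json.dumps(gj))


# ---------------------------------------------------------------------------
# Grid operators
# ---------------------------------------------------------------------------

def euclidean_distance(features: FeatureSet, spec: GridSpec) -> GridLayer:
    """Distance (m) from every cell center to the nearest feature.

    Cells inside polygon features get distance 0. Computed with shapely's
    vectorised geometry distance, so it is exact (not a raster
    approximation on cell hops).
    """
    if not features.geometries:
        raise ValueError("empty feature set")
    x, y = spec.cell_centers()
    pts = shapely.points(x.ravel(), y.ravel())
    target = shapely.union_all(np.asarray(features.geometries, dtype=object))
    dist = shapely.distance(pts, target).reshape(spec.n_rows, spec.n_cols)
    return GridLayer(spec, dist)


def _edge_padded(values: np.ndarray) -> np.ndarray:
    return np.pad(values, 1, mode="edge")


def terrain_derivatives(
    dem: GridLayer, relief_window: int = 5
) -> tuple[GridLayer, GridLayer, GridLayer]:
    """Slope (deg), aspect (deg clockwise from north) and local relief (m).

    Slope and aspect use Horn's third-order finite difference on the 3x3
    neighbourhood (edge rows/columns are edge-replicated). Flat cells get
    the aspect sentinel ``FLAT_ASPECT`` (-1). Relief is the focal max minus
    min of the DEM over a square ``relief_window`` x ``relief_window``
    window, ignoring nodata neighbours.

    Nodata: slope/aspect are nodata wherever any 3x3 neighbour is nodata;
    relief is nodata where the center cell is.
    """
    if dem.spec.n_rows < 3 or dem.spec.n_cols < 3:
        raise ValueError("terrain derivatives need at least a 3x3 grid")
    if relief_window < 1 or relief_window % 2 == 0:
        raise ValueError("relief_window must be a positive odd integer")

    z = np.where(dem.mask, np.nan, dem.values.astype(float))
    p = _edge_padded(z)
    cell = dem.spec.cell_size
    a, b, c = p[:-2, :-2], p[:-2, 1:-1], p[:-2, 2:]
    d, f = p[1:-1, :-2], p[1:-1, 2:]
    g, h, i = p[2:, :-2], p[2:, 1:-1], p[2:, 2:]

    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    # row 0 is north, so the "top" row of the window is the northern one
    dz_dy_north = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cell)

    grad = np.hypot(dz_dx, dz_dy_north)
    slope = np.degrees(np.arctan(grad))
    # azimuth of the downslope direction, clockwise from north
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy_north)) % 360.0
    aspect = np.where(grad == 0, FLAT_ASPECT, aspect)

    # any nodata in the 3x3 stencil propagates (Horn's stencil omits the
    # center cell, so mask it explicitly too)
    bad = np.isnan(slope) | dem.mask
    slope = np.where(bad, dem.nodata, slope)
    aspect = np.where(bad, dem.nodata, aspect)

    w = relief_window
    zmax = ndimage.maximum_filter(np.where(np.isnan(z), -np.inf, z), size=w)
    zmin = ndimage.minimum_filter(np.where(np.isnan(z), np.inf, z), size=w)
    relief = np.where(dem.mask, dem.nodata, zmax - zmin)

    mk = lambda v: GridLayer(dem.spec, v, nodata=dem.nodata)
    return mk(slope), mk(aspect), mk(relief)
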