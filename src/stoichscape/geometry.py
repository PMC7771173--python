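"""Scales of foraging: home-range/study-area polygons and availability samples.

Minimum convex polygons (MCPs) delineate the study area (landscape scale)
and individual home ranges; random and uniform-grid point samples provide
"available" locations at the landscape and home-range extents.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon

from .exceptions import (
    DegenerateGeometryError,
    EmptyRegionError,
    ExtentError,
    GeometryError,
    ValidationError,
)
from .rasters import ElementalRaster

log = logging.getLogger(__name__)

__all__ = [
    "MCPolygon",
    "SamplePoints",
    "make_mcp",
    "sample_random_points",
    "sample_grid_points",
    "extract_values",
]


@dataclass
class MCPolygon:
    """A minimum convex polygon home range or study-area boundary.

    The ``level`` fraction of points closest to the arithmetic centroid is
    retained and hulled; ``area_km2`` is the hull area in km^2 (inputs are
    planar meters).
    """

    polygon: Polygon
    level: float
    area_km2: float
    n_points_used: int
    n_points_total: int

    @property
    def wkt(self) -> str:
        return self.polygon.wkt


@dataclass
class SamplePoints:
    """A set of sampled locations with its sampling design metadata."""

    x: np.ndarray
    y: np.ndarray
    design: str  # random | grid | fixes
    role: str  # used | available
    scale: str  # landscape | home_range
    density_per_km2: float | None = None

    def __len__(self) -> int:
        return len(self.x)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "role": self.role,
                "scale": self.scale,
                "design": self.design,
            }
        )


def make_mcp(points, level: float = 0.95) -> MCPolygon:
    """Minimum convex polygon around the ``level`` fraction of points.

    Peeling removes the points farthest from the centroid (the arithmetic
    mean of all points, computed once); the ``ceil(level * n)`` closest
    points are retained and their convex hull returned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    if not 0 < level <= 1:
        raise ValidationError("level must be in (0, 1]")
    n = len(pts)
    keep = math.ceil(level * n)
    centroid = pts.mean(axis=0)
    d = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    order = np.argsort(d, kind="stable")
    retained = pts[order[:keep]]
    distinct = np.unique(retained, axis=0)
    if len(distinct) < 3:
        raise DegenerateGeometryError("fewer than 3 distinct points after peeling")
    hull = MultiPoint(retained).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateGeometryError("retained points are collinear; hull is degenerate")
    return MCPolygon(
        polygon=hull,
        level=level,
        area_km2=hull.area / 1e6,
        n_points_used=keep,
        n_points_total=n,
    )


def _as_polygon(polygon):
    if isinstance(polygon, MCPolygon):
        return polygon.polygon
    if isinstance(polygon, dict):
        return shapely.geometry.shape(polygon)
    if isinstance(polygon, str):
        return shapely.from_wkt(polygon)
    return polygon


def _count_from_density(area_km2: float, density_per_km2: float) -> int:
    # nearest integer, ties to even (Python round)
    return round(area_km2 * density_per_km2)


def sample_random_points(
    polygon,
    density_per_km2: float,
    mask_raster: ElementalRaster | None = None,
    seed: int | np.random.Generator = 0,
    scale: str = "landscape",
    role: str = "available",
) -> SamplePoints:
    """Uniform random points in a polygon at a nominal density (points/km^2).

    Points are rejection-sampled over the polygon's bounding box and, when a
    mask raster is given, restricted to non-nodata cells, so the nominal
    count lands entirely in valid habitat.
    """
    if density_per_km2 <= 0:
        raise ValidationError("density must be positive")
    poly = _as_polygon(polygon)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = _count_from_density(poly.area / 1e6, density_per_km2)
    if n == 0:
        log.warning("requested density rounds to 0 points; returning empty sample")
        return SamplePoints(
            np.empty(0), np.empty(0), "random", role, scale, density_per_km2
        )
    minx, miny, maxx, maxy = poly.bounds
    xs, ys = [], []
    got = 0
    empty_rounds = 0
    while got < n:
        m = max(4 * (n - got), 256)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        ok = shapely.covers(poly, shapely.points(cx, cy))
        if mask_raster is not None:
            ok &= mask_raster.is_valid_at(cx, cy)
        k = int(ok.sum())
        if k == 0:
            empty_rounds += 1
            if empty_rounds >= 100:
                raise EmptyRegionError(
                    "polygon contains no valid habitat (rejection sampling exhausted)"
                )
            continue
        empty_rounds = 0
        take = min(k, n - got)
        xs.append(cx[ok][:take])
        ys.append(cy[ok][:take])
        got += take
    return SamplePoints(
        np.concatenate(xs), np.concatenate(ys), "random", role, scale, density_per_km2
    )


def sample_grid_points(
    polygon,
    density_per_km2: float,
    mask_raster: ElementalRaster | None = None,
    scale: str = "home_range",
    role: str = "used",
) -> SamplePoints:
    """Uniform square-lattice points in a polygon at a nominal density.

    Lattice spacing is ``1000 / sqrt(density)`` meters; nodes sit at
    cell centers of a lattice anchored at the polygon envelope's lower-left
    corner (first node half a spacing in, no jitter, for reproducibility —
    corner-anchored nodes would overshoot the nominal density through the
    envelope boundary). Nodes outside the polygon or on nodata cells are
    discarded.
    """
    if density_per_km2 <= 0:
        raise ValidationError("density must be positive")
    poly = _as_polygon(polygon)
    spacing = 1000.0 / math.sqrt(density_per_km2)
    minx, miny, maxx, maxy = poly.bounds
    nx = max(int(math.ceil((maxx - minx) / spacing)), 1)
    ny = max(int(math.ceil((maxy - miny) / spacing)), 1)
    gx = minx + spacing * (0.5 + np.arange(nx))
    gy = miny + spacing * (0.5 + np.arange(ny))
    gx = gx[gx <= maxx]
    gy = gy[gy <= maxy]
    X, Y = np.meshgrid(gx, gy)
    cx, cy = X.ravel(), Y.ravel()
    ok = shapely.covers(poly, shapely.points(cx, cy))
    if mask_raster is not None:
        ok &= mask_raster.is_valid_at(cx, cy)
    return SamplePoints(cx[ok], cy[ok], "grid", role, scale, density_per_km2)


def extract_values(
    points,
    raster_c: ElementalRaster,
    raster_n: ElementalRaster,
) -> pd.DataFrame:
    """Extract C and N cell values at each point.

    ``points`` may be a SamplePoints, an (n, 2) array, or a DataFrame with
    x/y columns. Rows whose location falls on a nodata cell get NaN values
    and ``valid=False`` (to be dropped by the caller); a point outside the
    raster extent is an error.
    """
    if not raster_c.same_grid(raster_n):
        raise GeometryError("C and N rasters are not aligned")
    if isinstance(points, SamplePoints):
        x, y = points.x, points.y
    elif isinstance(points, pd.DataFrame):
        x = np.asarray(points["x"], dtype=float)
        y = np.asarray(points["y"], dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    inside = raster_c.in_extent(x, y)
    if not np.all(inside):
        i = int(np.argmin(inside))
        raise ExtentError(f"point ({x[i]}, {y[i]}) lies outside the raster extent")
    c = raster_c.value_at(x, y)
    n = raster_n.value_at(x, y)
    valid = ~(np.isnan(c) | np.isnan(n))
    return pd.DataFrame({"x": x, "y": y, "C": c, "N": n, "valid": valid})
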