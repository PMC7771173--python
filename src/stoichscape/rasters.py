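"""Elemental landscape layers.

Gridded surfaces of forage quantity (carbon, log g/m^2) and quality
(nitrogen, %) on a planar 30 m grid, plus the linear stoichiometric
distribution model (StDM) machinery used to predict them from landscape
covariates, a correlated Gaussian-random-field simulator for synthetic
landscapes, and within-polygon descriptive statistics.

Grid convention: cell ``(r, c)`` covers the half-open square
``[origin_x + c*px, origin_x + (c+1)*px) x [origin_y + r*px, origin_y + (r+1)*px)``;
row 0 is the southernmost row. All coordinates are planar meters.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .exceptions import (
    EmptyRegionError,
    GeometryError,
    SingularityError,
    UndefinedStatisticError,
    ValidationError,
)

MEASURES = ("carbon_log_quantity", "nitrogen_pct")

__all__ = [
    "ElementalRaster",
    "CovariateStack",
    "StDMModel",
    "fit_stdm",
    "predict_stdm",
    "simulate_elemental_pair",
    "polygon_stats",
    "pearson_cn",
    "read_grid",
    "write_grid",
]


@dataclass
class ElementalRaster:
    """A single-band gridded elemental surface with a nodata mask.

    Parameters
    ----------
    origin_x, origin_y
        Planar coordinates (m) of the grid's lower-left corner.
    pixel_size
        Cell edge length in meters (30 m patches by default).
    values
        ``(n_rows, n_cols)`` array of cell values; row 0 is the south edge.
    nodata_mask
        Boolean array, ``True`` where the surface is unpredicted (water,
        wetland, non-forest); values there are ignored.
    measure
        ``"carbon_log_quantity"`` (log g/m^2) or ``"nitrogen_pct"`` (%).
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    values: np.ndarray
    nodata_mask: np.ndarray = None
    measure: str = "carbon_log_quantity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("raster values must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise GeometryError("nodata mask shape does not match values")
        if not np.all(np.isfinite(self.values[~self.nodata_mask])):
            raise ValidationError("non-finite values outside the nodata mask")
        if self.measure not in MEASURES:
            raise ValidationError(f"unknown measure {self.measure!r}")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the full grid extent."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y + self.n_rows * self.pixel_size,
        )

    def same_grid(self, other: "ElementalRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.origin_x, other.origin_x)
            and math.isclose(self.origin_y, other.origin_y)
            and math.isclose(self.pixel_size, other.pixel_size)
        )

    def cell_index(self, x, y):
        """Row/col of the cell containing each point (half-open convention).

        Points on a shared edge belong to the cell to the right/above.
        Returns integer arrays; no bounds check is performed here.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.pixel_size).astype(int)
        row = np.floor((y - self.origin_y) / self.pixel_size).astype(int)
        return row, col

    def in_extent(self, x, y):
        row, col = self.cell_index(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def is_valid_at(self, x, y):
        """True where the point is inside the extent and not nodata."""
        row, col = self.cell_index(x, y)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out = np.zeros(np.shape(ok), dtype=bool)
        out[ok] = ~self.nodata_mask[row[ok], col[ok]]
        return out

    def value_at(self, x, y):
        """Cell value containing each point; nodata cells yield NaN."""
        row, col = self.cell_index(x, y)
        scalar = np.ndim(row) == 0
        row, col = np.atleast_1d(row), np.atleast_1d(col)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out = np.full(row.shape, np.nan)
        rr, cc = row[ok], col[ok]
        vals = self.values[rr, cc].copy()
        vals[self.nodata_mask[rr, cc]] = np.nan
        out[ok] = vals
        return float(out[0]) if scalar else out

    def cell_centers(self):
        """(X, Y) meshgrid arrays of all cell centers, shape (n_rows, n_cols)."""
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        ys = self.origin_y + (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)


# ---------------------------------------------------------------------------
# plain-text grid I/O (fixture-friendly; no binary formats)

_NODATA = -9999.0


def write_grid(raster: ElementalRaster, path) -> None:
    """Write a raster to the package's plain-text grid format."""
    buf = io.StringIO()
    buf.write(f"ncols {raster.n_cols}\n")
    buf.write(f"nrows {raster.n_rows}\n")
    buf.write(f"origin_x {raster.origin_x!r}\n")
    buf.write(f"origin_y {raster.origin_y!r}\n")
    buf.write(f"pixel_size {raster.pixel_size!r}\n")
    buf.write(f"nodata {_NODATA!r}\n")
    buf.write(f"measure {raster.measure}\n")
    vals = raster.values.copy()
    vals[raster.nodata_mask] = _NODATA
    for row in vals:  # row 0 first (south edge)
        buf.write(" ".join(repr(float(v)) for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_grid(path) -> ElementalRaster:
    """Read a raster written by :func:`write_grid`."""
    with open(path) as fh:
        header = {}
        for _ in range(7):
            key, val = fh.readline().split(maxsplit=1)
            header[key] = val.strip()
        vals = np.loadtxt(fh, ndmin=2)
    nodata = float(header["nodata"])
    mask = vals == nodata
    vals = vals.astype(float)
    vals[mask] = np.nan
    vals[mask] = 0.0
    return ElementalRaster(
        origin_x=float(header["origin_x"]),
        origin_y=float(header["origin_y"]),
        pixel_size=float(header["pixel_size"]),
        values=vals,
        nodata_mask=mask,
        measure=header["measure"],
    )


# ---------------------------------------------------------------------------
# StDM: Gaussian linear model of an elemental measure on landscape covariates

#: the six landscape predictors and their declared categorical levels
DEFAULT_CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "landcover": ("coniferous", "other"),
    "stand_height": ("0-6.5m", "6.6-9.5m", "9.6-12.5m", "12.6-21.5m"),
    "dominant_species": ("balsam_fir", "mixed_fir", "mixed_spruce"),
}
DEFAULT_CONTINUOUS = ("normalized_aspect", "slope", "elevation")


@dataclass
class CovariateStack:
    """Aligned covariate layers sharing one grid geometry and nodata mask.

    ``continuous`` maps covariate name to a float array; ``categorical`` maps
    name to an integer-code array indexing into ``levels[name]`` (code 0 is
    the reference level).
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    continuous: dict[str, np.ndarray]
    categorical: dict[str, np.ndarray] = field(default_factory=dict)
    levels: dict[str, tuple[str, ...]] = field(default_factory=dict)
    nodata_mask: np.ndarray = None

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.continuous.values()}
        shapes |= {a.shape for a in self.categorical.values()}
        if len(shapes) != 1:
            raise GeometryError("covariate layers do not share one grid shape")
        self.shape = shapes.pop()
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.shape, dtype=bool)
        if self.nodata_mask.shape != self.shape:
            raise GeometryError("nodata mask shape mismatch")
        for name, arr in self.categorical.items():
            lv = self.levels.get(name)
            if lv is None:
                raise ValidationError(f"categorical {name!r} has no declared levels")
            codes = arr[~self.nodata_mask]
            if codes.size and (codes.min() < 0 or codes.max() >= len(lv)):
                raise ValidationError(
                    f"categorical {name!r} takes codes outside its declared levels"
                )

    def to_frame(self) -> pd.DataFrame:
        """Flatten valid cells into a covariate table (one row per cell)."""
        keep = ~self.nodata_mask.ravel()
        data = {n: a.ravel()[keep] for n, a in self.continuous.items()}
        for n, a in self.categorical.items():
            lv = np.asarray(self.levels[n], dtype=object)
            data[n] = lv[a.ravel()[keep].astype(int)]
        return pd.DataFrame(data)


@dataclass
class StDMModel:
    """A fitted (or specified) stoichiometric distribution model.

    A Gaussian identity-link linear model of one elemental measure on the
    landscape predictors; categorical predictors use reference-level dummy
    coding with the first declared level as reference. Coefficient keys are
    either a continuous covariate name or ``"name[level]"`` for a
    non-reference categorical level.
    """

    response: str
    intercept: float
    coefficients: dict[str, float]
    residual_sd: float = 0.0
    r_squared: float | None = None
    levels: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be >= 0")

    def term_names(self) -> list[str]:
        return list(self.coefficients)


def _design_matrix(
    frame: pd.DataFrame,
    continuous: Sequence[str],
    levels: Mapping[str, Sequence[str]],
) -> tuple[np.ndarray, list[str]]:
    """Intercept + continuous columns + dummy columns (reference = level 0)."""
    cols = [np.ones(len(frame))]
    names = ["intercept"]
    for name in continuous:
        cols.append(np.asarray(frame[name], dtype=float))
        names.append(name)
    for name, lvls in levels.items():
        vals = np.asarray(frame[name])
        unknown = set(np.unique(vals)) - set(lvls)
        if unknown:
            raise ValidationError(
                f"unknown level(s) {sorted(unknown)} for categorical {name!r}"
            )
        for lvl in lvls[1:]:
            cols.append((vals == lvl).astype(float))
            names.append(f"{name}[{lvl}]")
    return np.column_stack(cols), names


def fit_stdm(
    plots: pd.DataFrame,
    response: str,
    continuous: Sequence[str] = DEFAULT_CONTINUOUS,
    categorical_levels: Mapping[str, Sequence[str]] | None = None,
) -> StDMModel:
    """Fit a Gaussian linear StDM to plot-level data by least squares.

    Parameters
    ----------
    plots
        One row per field plot: covariate columns plus the ``response`` column.
    response
        Name of the elemental response column (and the fitted model's measure).

    Raises
    ------
    SingularityError
        If the design matrix is rank deficient; the message names the
        offending columns.
    """
    levels = dict(
        categorical_levels
        if categorical_levels is not None
        else {k: v for k, v in DEFAULT_CATEGORICAL_LEVELS.items() if k in plots}
    )
    cont = [c for c in continuous if c in plots]
    X, names = _design_matrix(plots, cont, levels)
    y = np.asarray(plots[response], dtype=float)
    n, p = X.shape
    if n < p:
        raise ValidationError(f"need at least {p} rows to fit {p} parameters")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the columns that QR pivoting relegates past the numerical rank
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[rank:]]
        raise SingularityError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(n - p, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    return StDMModel(
        response=response,
        intercept=float(beta[0]),
        coefficients=dict(zip(names[1:], beta[1:].astype(float))),
        residual_sd=residual_sd,
        r_squared=r2,
        levels={k: tuple(v) for k, v in levels.items()},
    )


def predict_stdm(
    model: StDMModel,
    covs: CovariateStack,
    noise_seed: int | None = None,
) -> ElementalRaster:
    """Predict an elemental surface from covariates under a linear StDM.

    If ``noise_seed`` is given, per-cell Gaussian residual noise
    ``N(0, residual_sd^2)`` is added, emulating prediction-surface scatter.
    Cells where any covariate is nodata are nodata in the output.
    """
    pred = np.full(covs.shape, model.intercept, dtype=float)
    for name, coef in model.coefficients.items():
        if "[" in name:
            cov_name, lvl = name[:-1].split("[", 1)
            if cov_name not in covs.categorical:
                raise ValidationError(f"model term {name!r} missing from covariate stack")
            lvls = covs.levels[cov_name]
            if lvl not in lvls:
                raise ValidationError(f"unknown categorical level {lvl!r} for {cov_name!r}")
            pred += coef * (covs.categorical[cov_name] == lvls.index(lvl))
        else:
            if name not in covs.continuous:
                raise ValidationError(f"model term {name!r} missing from covariate stack")
            pred += coef * covs.continuous[name]
    if noise_seed is not None and model.residual_sd > 0:
        rng = np.random.default_rng(noise_seed)
        pred += rng.normal(0.0, model.residual_sd, size=covs.shape)
    pred[covs.nodata_mask] = 0.0
    measure = model.response if model.response in MEASURES else "carbon_log_quantity"
    return ElementalRaster(
        origin_x=covs.origin_x,
        origin_y=covs.origin_y,
        pixel_size=covs.pixel_size,
        values=pred,
        nodata_mask=covs.nodata_mask.copy(),
        measure=measure,
    )


# ---------------------------------------------------------------------------
# synthetic correlated elemental surfaces


def _smooth_standard_field(rng, shape, sigma_px):
    z = rng.standard_normal(shape)
    if sigma_px > 0:
        z = ndimage.gaussian_filter(z, sigma_px, mode="wrap")
    z = z - z.mean()
    sd = z.std()
    if sd == 0:  # pathological tiny grid; fall back to white noise
        z = rng.standard_normal(shape)
        z -= z.mean()
        sd = z.std()
    return z / sd


def simulate_elemental_pair(
    n_rows: int,
    n_cols: int,
    *,
    origin_x: float = 0.0,
    origin_y: float = 0.0,
    pixel_size: float = 30.0,
    target_mean_c: float = -1.65,
    target_sd_c: float = 0.89,
    target_mean_n: float = 2.78,
    target_sd_n: float = 0.28,
    target_corr: float = -0.01,
    spatial_range: float = 90.0,
    seed: int | np.random.Generator = 0,
    nodata_mask: np.ndarray | None = None,
) -> tuple[ElementalRaster, ElementalRaster]:
    """Simulate aligned carbon and nitrogen surfaces with exact sample moments.

    Two smoothed Gaussian random fields are generated; the second is
    empirically orthogonalized against the first and the pair is mixed with
    weights ``(rho, sqrt(1 - rho^2))``, so the sample cell-wise Pearson
    correlation equals ``target_corr`` exactly, as do the sample means and
    standard deviations after affine rescaling. ``spatial_range`` (m) is the
    Gaussian smoothing length scale; 0 gives white noise. Defaults reproduce
    the pooled two-study-area landscape summary (C mean -1.65 log g/m^2,
    SD 0.89; N mean 2.78 %, SD 0.28; r = -0.01).
    """
    if abs(target_corr) > 1:
        raise ValidationError("|target_corr| must be <= 1")
    if target_sd_c < 0 or target_sd_n < 0:
        raise ValidationError("target SDs must be >= 0")
    if spatial_range < 0:
        raise ValidationError("spatial_range must be >= 0")
    if (target_sd_c == 0 or target_sd_n == 0) and target_corr != 0:
        raise ValidationError("nonzero correlation is impossible with a zero SD")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    shape = (n_rows, n_cols)
    sigma_px = spatial_range / pixel_size
    z1 = _smooth_standard_field(rng, shape, sigma_px)
    z2 = _smooth_standard_field(rng, shape, sigma_px)
    # empirical orthogonalization: exact zero sample covariance with z1
    z2 = z2 - (z2 * z1).mean() * z1
    z2 -= z2.mean()
    z2 /= z2.std()
    rho = target_corr
    zn = rho * z1 + math.sqrt(1.0 - rho * rho) * z2
    zn -= zn.mean()
    zn /= zn.std()

    vals_c = target_mean_c + target_sd_c * z1
    vals_n = target_mean_n + target_sd_n * zn
    if nodata_mask is None:
        nodata_mask = np.zeros(shape, dtype=bool)
    common = dict(
        origin_x=origin_x, origin_y=origin_y, pixel_size=pixel_size
    )
    rc = ElementalRaster(
        values=vals_c, nodata_mask=nodata_mask.copy(),
        measure="carbon_log_quantity", **common,
    )
    rn = ElementalRaster(
        values=vals_n, nodata_mask=nodata_mask.copy(),
        measure="nitrogen_pct", **common,
    )
    return rc, rn


# ---------------------------------------------------------------------------
# within-polygon descriptive statistics


def _cells_in_polygon(raster: ElementalRaster, polygon) -> np.ndarray:
    """Boolean mask of cells whose centers fall inside the polygon.

    Uses ``covers`` so centers on the polygon boundary count as inside.
    Restricted to the polygon envelope for speed.
    """
    polygon = shapely.geometry.shape(polygon) if isinstance(polygon, dict) else polygon
    minx, miny, maxx, maxy = polygon.bounds
    px = raster.pixel_size
    c0 = max(int(math.floor((minx - raster.origin_x) / px - 0.5)), 0)
    c1 = min(int(math.ceil((maxx - raster.origin_x) / px + 0.5)), raster.n_cols)
    r0 = max(int(math.floor((miny - raster.origin_y) / px - 0.5)), 0)
    r1 = min(int(math.ceil((maxy - raster.origin_y) / px + 0.5)), raster.n_rows)
    mask = np.zeros(raster.values.shape, dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    xs = raster.origin_x + (np.arange(c0, c1) + 0.5) * px
    ys = raster.origin_y + (np.arange(r0, r1) + 0.5) * px
    X, Y = np.meshgrid(xs, ys)
    pts = shapely.points(X.ravel(), Y.ravel())
    inside = shapely.covers(polygon, pts).reshape(X.shape)
    mask[r0:r1, c0:c1] = inside
    return mask


def polygon_stats(raster: ElementalRaster, polygon):
    """Mean, median, sample SD, and cell count of a raster within a polygon.

    Statistics are computed over non-nodata cells whose centers fall inside
    (or on the boundary of) the polygon.
    """
    sel = _cells_in_polygon(raster, polygon) & ~raster.nodata_mask
    vals = raster.values[sel]
    if vals.size == 0:
        raise EmptyRegionError("polygon overlaps no non-nodata cells")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), float(np.median(vals)), sd, int(vals.size)


def pearson_cn(raster_c: ElementalRaster, raster_n: ElementalRaster, polygon) -> float:
    """Cell-wise Pearson correlation of two aligned layers within a polygon."""
    if not raster_c.same_grid(raster_n):
        raise GeometryError("rasters are not on the same grid")
    sel = (
        _cells_in_polygon(raster_c, polygon)
        & ~raster_c.nodata_mask
        & ~raster_n.nodata_mask
    )
    a = raster_c.values[sel]
    b = raster_n.values[sel]
    if a.size < 3:
        raise EmptyRegionError("need >= 3 jointly valid cells in the polygon")
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("zero variance in one layer; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])
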