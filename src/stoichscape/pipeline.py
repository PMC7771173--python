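"""End-to-end multiscale selection pipeline.

Orchestrates the three foraging scales on cleaned tracks and elemental
rasters:

* landscape (2nd order): used = home-range grid points (70/km^2),
  available = random points in the study-area MCP (22/km^2); logistic RSF
  per study area, plus a pooled fit when there are several areas;
* home range (3rd order): used = GPS fixes, available = home-range grid
  points; logistic RSF per individual plus pooled;
* patch (3.5th order): iSSA strata (1 used + 10 available 2-h steps)
  and conditional logistic regression per individual plus pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import RunConfig
from .exceptions import UndefinedStatisticError
from .geometry import MCPolygon, extract_values, make_mcp, sample_grid_points, sample_random_points
from .movement import filter_season, filter_to_predicted
from .rasters import ElementalRaster, pearson_cn
from .selection import (
    ISSA_TERMS,
    RSF_TERMS,
    SelectionFit,
    fit_conditional_logit,
    fit_movement_kernel,
    fit_rsf,
    generate_available_steps,
    steps_from_track,
)
from .tradeoff import TradeoffRecord

log = logging.getLogger(__name__)

__all__ = ["MultiscaleResult", "run_multiscale", "fits_to_frame"]


@dataclass
class MultiscaleResult:
    """Fits plus the geometry and context needed for trade-off synthesis."""

    fits: list[SelectionFit]
    home_ranges: dict[str, MCPolygon]
    study_areas: dict[str, MCPolygon]
    cn_pearson: dict[str, float]  # per unit (animal or area) within its polygon
    config: RunConfig
    meta: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return fits_to_frame(self.fits)

    def tradeoff_records(
        self, labels: Mapping[str, Mapping[str, object]] | None = None
    ) -> list[TradeoffRecord]:
        """One record per unit x scale carrying the C/N/CxN coefficients."""
        records = []
        for f in self.fits:
            if not {"C", "N", "C:N"} <= set(f.terms):
                continue
            extra = dict(labels.get(f.unit_id, {})) if labels else {}
            records.append(
                TradeoffRecord(
                    unit_id=f.unit_id,
                    scale=f.scale,
                    beta_c=f.beta["C"],
                    beta_n=f.beta["N"],
                    beta_cxn=f.beta["C:N"],
                    se_c=f.se["C"],
                    se_n=f.se["N"],
                    se_cxn=f.se["C:N"],
                    pseudo_r2=f.pseudo_r2,
                    cn_pearson_r=self.cn_pearson.get(f.unit_id),
                    sex=extra.get("sex"),
                    year=extra.get("year"),
                )
            )
        return records


def fits_to_frame(fits: list[SelectionFit]) -> pd.DataFrame:
    """Flatten fits into the reporting table (scale, unit, U, A, betas, R^2)."""
    return pd.DataFrame([f.summary_row() for f in fits])


def _rsf_table(used_xy, avail_xy, raster_c, raster_n) -> pd.DataFrame:
    u = extract_values(used_xy, raster_c, raster_n)
    a = extract_values(avail_xy, raster_c, raster_n)
    u = u[u["valid"]].assign(response=1)
    a = a[a["valid"]].assign(response=0)
    return pd.concat([u, a], ignore_index=True)


def run_multiscale(
    tracks: pd.DataFrame,
    raster_c: ElementalRaster,
    raster_n: ElementalRaster,
    config: RunConfig | None = None,
    areas: Mapping[str, str] | None = None,
) -> MultiscaleResult:
    """Run the full three-scale selection analysis.

    Parameters
    ----------
    tracks
        All animals' relocations (columns animal_id, timestamp, x, y).
    areas
        Mapping of animal_id to study-area name; all animals share one
        study area when omitted. Study-area boundaries are MCPs around all
        fixes of the area's animals.

    Returns
    -------
    MultiscaleResult with per-unit and pooled fits at each scale.
    """
    config = config or RunConfig()
    rng_root = np.random.SeedSequence(config.seed)
    animals = sorted(tracks["animal_id"].unique())
    areas = dict(areas) if areas else {a: "area1" for a in animals}
    log.info(
        "run_multiscale: %d animals, seed=%d, mcp_level=%s, densities=(%s used-grid, %s avail)/km^2, "
        "n_avail_steps=%d, window=%s..%s",
        len(animals), config.seed, config.mcp_level,
        config.density_used_grid_per_km2, config.density_available_per_km2,
        config.n_avail_steps, config.window_start, config.window_end,
    )

    # --- cleaning: seasonal window, then restrict to predicted habitat
    w0, w1 = config.window
    n_raw = len(tracks)
    clean = filter_season(tracks, w0, w1)
    clean = filter_to_predicted(clean, raster_c)
    log.info("cleaning kept %d of %d fixes", len(clean), n_raw)

    # --- geometry at both extents
    home_ranges: dict[str, MCPolygon] = {}
    for aid in animals:
        pts = clean.loc[clean["animal_id"] == aid, ["x", "y"]].to_numpy()
        home_ranges[aid] = make_mcp(pts, config.mcp_level)
    study_areas: dict[str, MCPolygon] = {}
    for area in sorted(set(areas.values())):
        ids = [a for a in animals if areas[a] == area]
        pts = clean.loc[clean["animal_id"].isin(ids), ["x", "y"]].to_numpy()
        study_areas[area] = make_mcp(pts, config.mcp_level)

    cn_pearson: dict[str, float] = {}
    for unit, mcp in {**home_ranges, **study_areas}.items():
        try:
            cn_pearson[unit] = pearson_cn(raster_c, raster_n, mcp.polygon)
        except UndefinedStatisticError:
            cn_pearson[unit] = float("nan")

    fits: list[SelectionFit] = []
    seeds = {
        name: np.random.default_rng(s)
        for name, s in zip(("landscape", "patch"), rng_root.spawn(2))
    }

    # --- home-range grid points (used at landscape scale, available at HR scale)
    hr_grid = {
        aid: sample_grid_points(
            home_ranges[aid], config.density_used_grid_per_km2, raster_c
        )
        for aid in animals
    }

    # --- landscape scale
    area_tables = []
    for area, mcp in study_areas.items():
        avail = sample_random_points(
            mcp,
            config.density_available_per_km2,
            raster_c,
            seed=seeds["landscape"],
        )
        used_xy = np.vstack(
            [
                np.column_stack([hr_grid[a].x, hr_grid[a].y])
                for a in animals
                if areas[a] == area
            ]
        )
        table = _rsf_table(used_xy, np.column_stack([avail.x, avail.y]), raster_c, raster_n)
        area_tables.append(table)
        fits.append(fit_rsf(table, RSF_TERMS, unit_id=area, scale="landscape"))
    if len(study_areas) > 1:
        pooled = pd.concat(area_tables, ignore_index=True)
        fits.append(fit_rsf(pooled, RSF_TERMS, unit_id="pooled", scale="landscape"))

    # --- home-range scale
    hr_tables = []
    for aid in animals:
        fixes = clean.loc[clean["animal_id"] == aid, ["x", "y"]].to_numpy()
        g = hr_grid[aid]
        table = _rsf_table(fixes, np.column_stack([g.x, g.y]), raster_c, raster_n)
        hr_tables.append(table)
        fits.append(fit_rsf(table, RSF_TERMS, unit_id=aid, scale="home_range"))
    if len(animals) > 1:
        pooled = pd.concat(hr_tables, ignore_index=True)
        fits.append(fit_rsf(pooled, RSF_TERMS, unit_id="pooled", scale="home_range"))

    # --- patch scale (iSSA), per-individual movement kernels
    strata_tables = []
    for aid in animals:
        track = clean[clean["animal_id"] == aid]
        steps = steps_from_track(
            track, config.fix_interval_hours, config.step_tolerance_minutes
        )
        kernel = fit_movement_kernel(steps)
        strata = generate_available_steps(
            steps,
            kernel,
            raster_c,
            raster_n,
            n_avail=config.n_avail_steps,
            seed=seeds["patch"],
            min_candidates=config.min_candidates,
        )
        strata_tables.append(strata)
        fits.append(
            fit_conditional_logit(strata, ISSA_TERMS, unit_id=aid, scale="patch")
        )
    if len(animals) > 1:
        pooled = pd.concat(strata_tables, ignore_index=True)
        fits.append(
            fit_conditional_logit(pooled, ISSA_TERMS, unit_id="pooled", scale="patch")
        )

    meta = {
        "n_fixes_raw": n_raw,
        "n_fixes_clean": len(clean),
        "areas": areas,
        "pseudo_r2_flavor": "mcfadden",
    }
    return MultiscaleResult(
        fits=fits,
        home_ranges=home_ranges,
        study_areas=study_areas,
        cn_pearson=cn_pearson,
        config=config,
        meta=meta,
    )
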