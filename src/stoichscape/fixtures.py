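"""Deterministic end-to-end fixture generator.

Builds a small two-study-area dataset — correlated C/N elemental surfaces
with landscape-specific targets, plus step-selection-simulated moose tracks
with known coefficients — so the whole pipeline can be run and tested with
no external data. Everything derives from a single seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .movement import MovementModel, SimConfig, simulate_track, write_track_csv
from .rasters import ElementalRaster, simulate_elemental_pair, write_grid

__all__ = ["make_fixture_dataset"]

#: per-area elemental targets: C mean/SD (log g/m^2), N mean/SD (%), C-N r.
#: Values follow the two boreal study landscapes this package emulates.
AREA_TARGETS = {
    "PP": dict(target_mean_c=-1.92, target_sd_c=0.89,
               target_mean_n=2.82, target_sd_n=0.27, target_corr=0.11),
    "OMP": dict(target_mean_c=-1.41, target_sd_c=0.82,
                target_mean_n=2.74, target_sd_n=0.28, target_corr=-0.04),
}

#: known selection coefficients cycled over the animals in each area
TRUE_BETAS = [
    (1.0, -0.5, 0.0),
    (-0.5, 1.0, 0.5),
    (0.8, 0.3, -0.5),
    (0.0, 0.0, 0.0),
]

DEFAULT_MOVEMENT = dict(gamma_shape=2.0, gamma_scale=150.0, vm_mu=0.0, vm_kappa=0.5)


def make_fixture_dataset(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_animals_per_area: int = 4,
    n_fixes: int = 1500,
    grid_size: int = 200,
    pixel_size: float = 30.0,
    dropout_rate: float = 0.05,
    nodata_fraction: float = 0.03,
):
    """Generate rasters, tracks, and the generating truth record.

    Two study areas sit on one shared grid, separated by a nodata strip;
    each holds ``n_animals_per_area`` simulated animals whose tracks start
    in late May so the June 1 - July 16 cleaning window is exercised, with
    5% fix dropout creating real timestamp gaps.

    Returns ``(raster_c, raster_n, tracks, truth)``; when ``out_dir`` is
    given the same objects are also written as plain-text grids, a track
    CSV, and a truth JSON.
    """
    ss = np.random.SeedSequence(seed)
    s_land, s_track, s_mask = ss.spawn(3)
    gap = 10
    n_cols = 2 * grid_size + gap
    vals_c = np.zeros((grid_size, n_cols))
    vals_n = np.zeros((grid_size, n_cols))
    mask = np.ones((grid_size, n_cols), dtype=bool)
    rng_land = np.random.default_rng(s_land)
    rng_mask = np.random.default_rng(s_mask)
    area_names = list(AREA_TARGETS)
    offsets = {}
    for i, area in enumerate(area_names):
        rc, rn = simulate_elemental_pair(
            grid_size, grid_size,
            pixel_size=pixel_size,
            spatial_range=3 * pixel_size,
            seed=rng_land,
            **AREA_TARGETS[area],
        )
        c0 = i * (grid_size + gap)
        offsets[area] = c0
        vals_c[:, c0 : c0 + grid_size] = rc.values
        vals_n[:, c0 : c0 + grid_size] = rn.values
        block = rng_mask.random((grid_size, grid_size)) < nodata_fraction
        mask[:, c0 : c0 + grid_size] = block
    raster_c = ElementalRaster(0.0, 0.0, pixel_size, vals_c, mask, "carbon_log_quantity")
    raster_n = ElementalRaster(0.0, 0.0, pixel_size, vals_n, mask, "nitrogen_pct")

    movement = MovementModel(**DEFAULT_MOVEMENT)
    rng_track = np.random.default_rng(s_track)
    tracks = []
    truth_animals = {}
    half = grid_size * pixel_size / 2.0
    for i, area in enumerate(area_names):
        cx = offsets[area] * pixel_size + half
        for j in range(n_animals_per_area):
            aid = f"{area}{j + 1}"
            bc, bn, bcn = TRUE_BETAS[j % len(TRUE_BETAS)]
            # start near the area's center, on a valid cell
            for _ in range(1000):
                sx = cx + rng_track.uniform(-half / 2, half / 2)
                sy = half + rng_track.uniform(-half / 2, half / 2)
                if bool(raster_c.is_valid_at(sx, sy)):
                    break
            sim = SimConfig(
                true_beta_c=bc, true_beta_n=bn, true_beta_cxn=bcn,
                n_steps=n_fixes - 1,
                dropout_rate=dropout_rate,
                start_x=sx, start_y=sy,
                start_time="2014-05-25T00:00:00Z",
            )
            tracks.append(
                simulate_track(raster_c, raster_n, movement, sim, aid, rng=rng_track)
            )
            truth_animals[aid] = {
                "area": area, "beta_c": bc, "beta_n": bn, "beta_cxn": bcn,
            }
    tracks = pd.concat(tracks, ignore_index=True)
    truth = {
        "seed": seed,
        "movement": DEFAULT_MOVEMENT,
        "area_targets": AREA_TARGETS,
        "animals": truth_animals,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_grid(raster_c, out / "carbon.grid")
        write_grid(raster_n, out / "nitrogen.grid")
        write_track_csv(tracks, out / "tracks.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return raster_c, raster_n, tracks, truth
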