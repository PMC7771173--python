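"""GPS tracks: simulation from a known step-selection process and hygiene.

The simulator is the generative mirror of the patch-scale analysis: at each
2-h step, candidate endpoints are drawn from a gamma (step length) x
von Mises (turn angle) movement kernel and one is chosen with probability
proportional to ``exp(bC*C + bN*N + bCxN*C*N)`` of the elemental values at
the endpoint. Because the generating coefficients are known, every
downstream selection model has a parameter-recovery oracle.

Tracks are pandas DataFrames with columns ``animal_id, timestamp, x, y``
(timestamps UTC, strictly increasing within an animal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SimulationError, ValidationError
from .rasters import ElementalRaster

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["animal_id", "timestamp", "x", "y"]

__all__ = [
    "MovementModel",
    "SimConfig",
    "simulate_track",
    "filter_time_window",
    "filter_season",
    "filter_to_predicted",
    "read_track_csv",
    "write_track_csv",
]


@dataclass
class MovementModel:
    """Gamma step-length and von Mises turn-angle movement kernel."""

    gamma_shape: float
    gamma_scale: float  # meters
    vm_mu: float = 0.0  # radians
    vm_kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.gamma_scale <= 0:
            raise ValidationError("gamma parameters must be positive")
        if self.vm_kappa < 0:
            raise ValidationError("vm_kappa must be >= 0")
        if not (-math.pi < self.vm_mu <= math.pi):
            raise ValidationError("vm_mu must lie in (-pi, pi]")

    @property
    def mean_step_length(self) -> float:
        return self.gamma_shape * self.gamma_scale


@dataclass
class SimConfig:
    """Truth container for a simulated track.

    ``true_beta_c``/``true_beta_n``/``true_beta_cxn`` weight the elemental
    values at candidate endpoints; ``n_candidates`` (default 50) is the
    simulator's kernel-approximation size, deliberately larger than the
    analysis's 10 available steps.
    """

    true_beta_c: float = 0.0
    true_beta_n: float = 0.0
    true_beta_cxn: float = 0.0
    n_steps: int = 1000
    fix_interval_hours: float = 2.0
    dropout_rate: float = 0.0
    start_x: float = 0.0
    start_y: float = 0.0
    start_time: str = "2014-06-01T00:00:00Z"
    n_candidates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.n_steps < 1:
            raise ValidationError("n_steps must be >= 1")
        if self.n_candidates < 1:
            raise ValidationError("n_candidates must be >= 1")


def _wrap_angle(a):
    """Wrap to (-pi, pi]."""
    out = np.mod(-np.asarray(a) + np.pi, 2 * np.pi)
    return -(out - np.pi)


def simulate_track(
    raster_c: ElementalRaster,
    raster_n: ElementalRaster,
    movement: MovementModel,
    sim: SimConfig,
    animal_id: str = "sim1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a GPS track by stepwise habitat-weighted kernel sampling.

    At each step ``n_candidates`` endpoints are drawn from the movement
    kernel relative to the previous heading; candidates landing outside
    predicted habitat are redrawn (up to 100 rounds, else the agent is
    deemed trapped); one endpoint is chosen with probability proportional
    to ``exp(bC*C + bN*N + bCxN*C*N)``. Fixes are then thinned by
    ``dropout_rate``, which creates real timestamp gaps.
    """
    rng = np.random.default_rng(sim.seed) if rng is None else rng
    if not bool(raster_c.is_valid_at(sim.start_x, sim.start_y)):
        raise ValidationError("start location is on nodata or outside the raster")
    K = sim.n_candidates
    x, y = float(sim.start_x), float(sim.start_y)
    heading = rng.uniform(-math.pi, math.pi)
    xs = np.empty(sim.n_steps + 1)
    ys = np.empty(sim.n_steps + 1)
    xs[0], ys[0] = x, y
    bc, bn, bcn = sim.true_beta_c, sim.true_beta_n, sim.true_beta_cxn
    for i in range(sim.n_steps):
        cand_x = np.empty(K)
        cand_y = np.empty(K)
        n_have = 0
        for _round in range(100):
            need = K - n_have
            lengths = rng.gamma(movement.gamma_shape, movement.gamma_scale, need)
            turns = rng.vonmises(movement.vm_mu, movement.vm_kappa, need)
            h = heading + turns
            ex = x + lengths * np.cos(h)
            ey = y + lengths * np.sin(h)
            ok = raster_c.is_valid_at(ex, ey)
            k = int(ok.sum())
            if k:
                cand_x[n_have : n_have + k] = ex[ok]
                cand_y[n_have : n_have + k] = ey[ok]
                n_have += k
            if n_have >= K:
                break
        if n_have == 0:
            raise SimulationError(
                f"agent trapped at step {i}: no valid candidate endpoint in 100 rounds"
            )
        cx, cy = cand_x[:n_have], cand_y[:n_have]
        c = raster_c.value_at(cx, cy)
        n = raster_n.value_at(cx, cy)
        w = bc * c + bn * n + bcn * c * n
        w -= w.max()
        p = np.exp(w)
        p /= p.sum()
        j = rng.choice(n_have, p=p)
        nx, ny = float(cx[j]), float(cy[j])
        if nx != x or ny != y:
            heading = math.atan2(ny - y, nx - x)
        x, y = nx, ny
        xs[i + 1], ys[i + 1] = x, y
    t0 = pd.Timestamp(sim.start_time)
    times = t0 + pd.to_timedelta(
        np.arange(sim.n_steps + 1) * sim.fix_interval_hours, unit="h"
    )
    track = pd.DataFrame(
        {"animal_id": animal_id, "timestamp": times, "x": xs, "y": ys}
    )
    if sim.dropout_rate > 0:
        keep = rng.random(len(track)) >= sim.dropout_rate
        keep[0] = True  # anchor the track start
        track = track[keep].reset_index(drop=True)
    return track


def filter_time_window(track: pd.DataFrame, start_date, end_date) -> pd.DataFrame:
    """Retain fixes whose calendar date lies in the closed [start, end] window."""
    dates = pd.to_datetime(track["timestamp"]).dt.date
    start = pd.Timestamp(start_date).date()
    end = pd.Timestamp(end_date).date()
    out = track[(dates >= start) & (dates <= end)].reset_index(drop=True)
    if out.empty and not track.empty:
        log.warning("time-window filter removed every fix")
    return out


def filter_season(
    track: pd.DataFrame,
    start_month_day: tuple[int, int] = (6, 1),
    end_month_day: tuple[int, int] = (7, 16),
) -> pd.DataFrame:
    """Retain fixes inside a month/day window applied within every year.

    Default is the early growing season (June 1 - July 16), the temporal
    window of the elemental prediction surfaces.
    """
    ts = pd.to_datetime(track["timestamp"])
    md = ts.dt.month * 100 + ts.dt.day
    lo = start_month_day[0] * 100 + start_month_day[1]
    hi = end_month_day[0] * 100 + end_month_day[1]
    out = track[(md >= lo) & (md <= hi)].reset_index(drop=True)
    if out.empty and not track.empty:
        log.warning("seasonal filter removed every fix")
    return out


def filter_to_predicted(df: pd.DataFrame, raster: ElementalRaster) -> pd.DataFrame:
    """Drop rows whose location falls on nodata (unpredicted habitat).

    Works for any frame with x/y columns (tracks, sample-point tables).
    """
    ok = raster.is_valid_at(
        np.asarray(df["x"], dtype=float), np.asarray(df["y"], dtype=float)
    )
    removed = int((~ok).sum())
    if removed:
        log.info("filter_to_predicted: removed %d of %d rows", removed, len(df))
    return df[ok].reset_index(drop=True)


def write_track_csv(track: pd.DataFrame, path) -> None:
    out = track.copy()
    ts = pd.to_datetime(out["timestamp"])
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize("UTC")
    out["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out[TRACK_COLUMNS].to_csv(path, index=False)


def read_track_csv(path) -> pd.DataFrame:
    track = pd.read_csv(path)
    track["timestamp"] = pd.to_datetime(track["timestamp"], utc=True)
    return track[TRACK_COLUMNS]
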