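"""Run configuration: study-design parameters with field defaults.

Defaults are the study conditions: 95% MCPs, available points at 22/km^2
(landscape), used grid points at 70/km^2 (home range), 10 available steps
per stratum, 2-h fix interval, and the June 1 - July 16 early-growing-season
window of the elemental prediction surfaces.
"""

from __future__ import annotations

import re
from dataclasses import asdict, dataclass, field, fields

import yaml

from .exceptions import ValidationError

CONFIG_VERSION = 1

_MMDD = re.compile(r"^(\d{2})-(\d{2})$")


def _parse_mmdd(s: str) -> tuple[int, int]:
    m = _MMDD.match(s)
    if not m:
        raise ValidationError(f"window date {s!r} is not MM-DD")
    month, day = int(m.group(1)), int(m.group(2))
    if not (1 <= month <= 12 and 1 <= day <= 31):
        raise ValidationError(f"window date {s!r} out of range")
    return month, day


@dataclass
class RunConfig:
    """Validated parameters for a multiscale selection run."""

    version: int = CONFIG_VERSION
    mcp_level: float = 0.95
    density_available_per_km2: float = 22.0
    density_used_grid_per_km2: float = 70.0
    n_avail_steps: int = 10
    fix_interval_hours: float = 2.0
    window_start: str = "06-01"
    window_end: str = "07-16"
    seed: int = 0
    output_dir: str = "results"
    step_tolerance_minutes: float = 1.0
    min_candidates: int = 3
    rasters: dict = field(default_factory=dict)  # optional file paths
    tracks: str | None = None
    simulation: dict = field(default_factory=dict)  # optional simulate block

    def __post_init__(self) -> None:
        if not 0 < self.mcp_level <= 1:
            raise ValidationError("mcp_level must be in (0, 1]")
        if self.density_available_per_km2 <= 0 or self.density_used_grid_per_km2 <= 0:
            raise ValidationError("densities must be positive")
        if self.n_avail_steps < 1:
            raise ValidationError("n_avail_steps must be >= 1")
        if self.fix_interval_hours <= 0:
            raise ValidationError("fix_interval_hours must be positive")
        _parse_mmdd(self.window_start)
        _parse_mmdd(self.window_end)

    @property
    def window(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return _parse_mmdd(self.window_start), _parse_mmdd(self.window_end)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; absent keys get defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config file must contain a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
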