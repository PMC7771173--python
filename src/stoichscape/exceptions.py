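"""Exception hierarchy for stoichscape.

All package errors derive from :class:`StoichscapeError` so callers can catch
one base class at pipeline boundaries.
"""


class StoichscapeError(Exception):
    """Base class for all package errors."""


class ValidationError(StoichscapeError, ValueError):
    """An input value is outside its documented domain."""


class GeometryError(StoichscapeError):
    """Raster grids or vector geometries are incompatible."""


class DegenerateGeometryError(GeometryError):
    """Too few distinct points to build the requested geometry."""


class EmptyRegionError(StoichscapeError):
    """A polygon overlaps no usable (non-nodata) raster cells."""


class ExtentError(StoichscapeError):
    """A point falls outside the raster extent."""


class SingularityError(StoichscapeError):
    """A design matrix is rank deficient; message names the collinear columns."""


class DegenerateFitError(StoichscapeError):
    """A distribution fit is impossible (e.g. zero-variance step lengths)."""


class InsufficientDataError(StoichscapeError):
    """Not enough observations for the requested analysis."""


class UndefinedStatisticError(StoichscapeError):
    """A statistic is undefined for this input (e.g. zero-variance correlation)."""


class SimulationError(StoichscapeError):
    """A simulation cannot proceed (e.g. the agent is trapped on nodata)."""
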