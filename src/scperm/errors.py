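"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`ScpermError`
so callers can distinguish pipeline failures from programming errors.
"""
from __future__ import annotations


class ScpermError(Exception):
    """Base class for all scperm errors."""


# --- I/O ---------------------------------------------------------------
class ParseError(ScpermError):
    """A text input could not be parsed; the message names the line."""


class EmptyInputError(ParseError):
    """A file contained metadata but no data rows."""


class FormatError(ScpermError):
    """A structured file violates its fixed layout (e.g. GRO atom count)."""


class SelectionSyntaxError(ScpermError):
    """Malformed atom-selection expression."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# --- planning / generation --------------------------------------------
class PlanningError(ScpermError):
    """Sampling-plan inputs are not mutually divisible."""


class LandscapeError(ScpermError):
    """A free-energy/diffusion landscape is nonphysical at a window."""


class FixtureError(ScpermError):
    """A toy-membrane request is geometrically impossible."""


# --- analysis ----------------------------------------------------------
class GapError(ScpermError):
    """Windows of the grid have no retained force samples."""


class PairingError(ScpermError):
    """Grid is not symmetric about the bilayer center; cannot symmetrize."""


class InsufficientDataError(ScpermError):
    """A series is too short for the requested lag range."""


class DegenerateSeriesError(ScpermError):
    """ACF has zero variance; convergence is undefined."""


class NonphysicalIntegralError(ScpermError):
    """The ACF time integral is non-positive; no diffusion coefficient."""


class ConvergenceError(ScpermError):
    """An ACF failed the decay-to-threshold convergence criterion."""


class PermeabilityError(ScpermError):
    """The resistance integral cannot be evaluated (e.g. D <= 0)."""


class ConfigError(ScpermError):
    """A run configuration failed validation."""


class StageError(ScpermError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
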