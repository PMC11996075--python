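"""Exception hierarchy shared across the pipeline.

Every stage raises a subclass of :class:`AortaflowError` so callers (and the
CLI) can map failures onto coarse exit codes without string matching.
"""


class AortaflowError(Exception):
    """Base class for all package errors."""


class GeometryError(AortaflowError):
    """A lumen, plane or orifice does not fit the grid it is placed on."""


class AliasingError(AortaflowError):
    """Peak speed exceeds the velocity-encoding limit; phase would wrap."""


class EstimationError(AortaflowError):
    """A statistical estimate is requested from an empty or degenerate sample."""


class FittingError(AortaflowError):
    """A least-squares design is singular or produced non-finite coefficients."""


class ConvergenceError(AortaflowError):
    """An iterative solve could not bracket or refine its root."""


class ConfigError(AortaflowError):
    """A run configuration failed validation; ``field`` names the offender."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")
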