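"""Exception hierarchy shared across the package."""


class NuquantError(Exception):
    """Base class for all package errors."""


class ParameterError(NuquantError, ValueError):
    """Invalid simulation or analysis parameters."""


class SegmentationError(NuquantError, RuntimeError):
    """Nucleus segmentation could not produce a usable mask."""


class ClassificationError(NuquantError, RuntimeError):
    """Intensity-class fitting or voxel labelling failed."""


class ConvergenceError(ClassificationError):
    """Equal-variance boundary fit did not reach the requested tolerance.

    Carries the diagnostics of the best iterate so callers can inspect how
    far the fit got.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class StatisticsError(NuquantError, ValueError):
    """A statistical test was requested on degenerate input."""


class InputError(NuquantError, ValueError):
    """Malformed external input (stack, alignment file, gene model...)."""
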