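"""Exception hierarchy shared across the pipeline stages."""


class GrassinvertError(Exception):
    """Base class for all package errors."""


class BandCoverageError(GrassinvertError, ValueError):
    """A spectrum (or wavelength grid) has no channel inside a band window."""


class CalibrationError(GrassinvertError, ValueError):
    """Reflectance calibration is impossible (panel signal <= dark current)."""


class UndefinedNdviError(GrassinvertError, ZeroDivisionError):
    """NDVI denominator nir + red is zero."""


class DomainError(GrassinvertError, ValueError):
    """An input lies outside the mathematically valid domain of an operation."""


class DegenerateModelError(GrassinvertError, ValueError):
    """A regression cannot be fitted (zero-variance regressor, c = 0, ...)."""


class PipelineStageError(GrassinvertError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
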