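"""Exception hierarchy shared across the pipeline."""


class TracheaPatError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSpecError(TracheaPatError):
    """A group specification cannot produce a valid (positive) draw."""


class GeometryError(TracheaPatError):
    """A geometric precondition is violated (object outside field of view, etc.)."""


class CoverageError(TracheaPatError):
    """Sinogram time axis does not cover the requested reconstruction grid."""


class SpectralLookupError(TracheaPatError, LookupError):
    """A (chromophore, wavelength) pair is absent from the extinction table."""


class SegmentationError(TracheaPatError):
    """No closed high-signal annulus could be segmented from the image."""


class DetectionError(TracheaPatError):
    """No peak above background was found."""


class ConfigError(TracheaPatError):
    """Experiment configuration failed validation.

    ``field`` holds the dotted path of the offending entry.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config error at '{field}': {message}")
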