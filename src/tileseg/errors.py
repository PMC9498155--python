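"""Exception hierarchy shared by all tileseg modules."""


class TileSegError(Exception):
    """Base class for all tileseg errors."""


class FormatError(TileSegError):
    """Raised when an input raster/annotation file has the wrong layout."""


class ParameterError(TileSegError):
    """Raised for invalid numeric parameters (factors, strides, thresholds)."""


class AnnotationValidationError(TileSegError):
    """Raised when annotations violate their invariants (e.g. tumor/normal overlap)."""

    def __init__(self, message, offending_pairs=None):
        super().__init__(message)
        self.offending_pairs = offending_pairs or []


class DataError(TileSegError):
    """Raised for degenerate data (empty class, missing artifact, shape mismatch)."""


class ConfigError(TileSegError):
    """Raised when a pipeline configuration fails validation."""
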