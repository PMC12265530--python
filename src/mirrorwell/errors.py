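"""Exception hierarchy shared across the package."""


class MirrorwellError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(MirrorwellError, ValueError):
    """Invalid physical geometry or optics parameters."""


class SchemaError(MirrorwellError, ValueError):
    """Keypoint table does not match the fixed 8-landmark schema."""


class FormatError(MirrorwellError, ValueError):
    """Malformed input file (bad header, non-monotone frame index, ...)."""


class FitError(MirrorwellError, RuntimeError):
    """Shape fitting (ellipse/ellipsoid/MTF) failed or input degenerate."""


class TotalInternalReflectionError(GeometryError):
    """Snell's law has no real solution for the requested refraction."""
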