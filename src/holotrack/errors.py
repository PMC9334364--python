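"""Exception hierarchy shared across the package."""


class HolotrackError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HolotrackError, ValueError):
    """Invalid configuration value (non-positive wavelength, bad plane set, ...)."""


class InvalidFieldError(HolotrackError, ValueError):
    """Optical field contains non-finite values."""


class DimensionError(HolotrackError, ValueError):
    """Array shapes incompatible with the configured sampling grid."""


class GeometryError(HolotrackError, ValueError):
    """Scene geometry violated: beads overlapping, outside the volume, ..."""


class DegenerateInputError(HolotrackError, ValueError):
    """Input carries no usable signal (all-zero hologram, empty mask, ...)."""


class ConcentrationInfeasibleError(GeometryError):
    """Rejection sampling could not place the requested beads without overlap."""
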