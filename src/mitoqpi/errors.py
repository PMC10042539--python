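"""Exception types shared across the package."""


class MitoQPIError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MitoQPIError, ValueError):
    """A parameter is outside its documented range."""


class InputError(MitoQPIError, ValueError):
    """Inputs are malformed or mutually inconsistent (shape, channel, schema)."""


class InsufficientDataError(MitoQPIError, ValueError):
    """Not enough observations to compute the requested quantity."""


class DegenerateFitError(MitoQPIError, RuntimeError):
    """A model fit cannot be performed (e.g. too few background pixels)."""


class PlacementError(MitoQPIError, ValueError):
    """A synthetic object does not fit on the rendering canvas."""


class GenerationError(MitoQPIError, RuntimeError):
    """Synthetic-data generation failed (e.g. overcrowded field of view)."""


class ResourceError(MitoQPIError, RuntimeError):
    """A configured resource cap was exceeded."""


class ConfigError(MitoQPIError, ValueError):
    """Configuration file invalid: unknown key or out-of-range value."""
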