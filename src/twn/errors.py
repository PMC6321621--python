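"""Exception hierarchy for the twn package."""


class TWNError(Exception):
    """Base class for all twn-specific errors."""


class ConfigurationError(TWNError):
    """A selector, region or config entry could not be resolved."""


class DegenerateGeometryError(TWNError):
    """Two interaction sites coincide; the pair energy is undefined."""


class GenerationError(TWNError):
    """A synthetic fixture failed its post-generation validation."""
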