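"""Exception hierarchy shared across the package."""


class PericellError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PericellError, ValueError):
    """A numeric argument violates a precondition (sign, range, shape)."""


class DegenerateGeometryError(PericellError, ValueError):
    """Well geometry that produces a non-physical medium column."""


class UnsupportedElementError(PericellError, ValueError):
    """Molecular formula contains an element with no isotope data."""


class ConfigError(PericellError, ValueError):
    """An analysis configuration is internally inconsistent."""
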