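"""Exception types shared across the package."""


class MemsoapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MemsoapError, ValueError):
    """A mapping / run configuration is malformed or incomplete."""


class MappingError(MemsoapError, ValueError):
    """A trajectory does not satisfy the lipid topology mapping."""


class ParameterError(MemsoapError, ValueError):
    """Descriptor or analysis parameters are invalid for the given input."""


class IncompatibilityError(MemsoapError, ValueError):
    """Two objects that must share parameters / grids / shapes do not."""


class DegenerateEnvironmentError(MemsoapError, ValueError):
    """An environment produced a zero (or otherwise unusable) descriptor."""


class InsufficientDataError(MemsoapError, ValueError):
    """Not enough samples / frames for the requested estimate."""
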