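"""Exception hierarchy shared across the package."""


class MitoscopeError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MitoscopeError, ValueError):
    """An invalid parameter or generator spec; the message names the field."""


class ValidationError(MitoscopeError, ValueError):
    """Input data violate a documented precondition."""


class GenerationError(MitoscopeError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""
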