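"""Exception types shared across the package."""


class AbnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AbnetError, ValueError):
    """An input violates a data contract (non-binary cell, duplicate id, ...)."""


class ConfigurationError(AbnetError, ValueError):
    """A configuration object is internally inconsistent or unusable."""


class UndefinedCorrelationError(AbnetError, ValueError):
    """A Pearson coefficient is undefined because one variable has zero variance."""


class UndefinedDiameterError(AbnetError, ValueError):
    """The diameter is undefined because the graph has no edges."""
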