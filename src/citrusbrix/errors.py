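"""Exception hierarchy shared across the package."""


class CitrusBrixError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CitrusBrixError, ValueError):
    """An argument violates a documented pre-condition."""


class DomainError(CitrusBrixError, ValueError):
    """A model form was evaluated outside its mathematical domain."""


class FittingError(CitrusBrixError, RuntimeError):
    """Model fitting failed (rank deficiency or non-convergence)."""


class ConfigError(CitrusBrixError, ValueError):
    """A simulation or run configuration is infeasible."""
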