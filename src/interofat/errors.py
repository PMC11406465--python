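"""Exception types shared across the package."""


class InterofatError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(InterofatError, ValueError):
    """A parameter violates its documented constraint."""


class EmptyInputError(InterofatError, ValueError):
    """An operation received no usable observations."""


class UndefinedScoreError(InterofatError, ValueError):
    """A score is mathematically undefined for the given input."""


class InsufficientTrialsError(InterofatError, ValueError):
    """Too few trials to compute the requested statistic."""


class InvalidInputError(InterofatError, ValueError):
    """Structured input (table, volume set, design) fails validation."""


class NotConvergedError(InterofatError, RuntimeError):
    """A numerical fit did not converge; diagnostics are attached."""
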