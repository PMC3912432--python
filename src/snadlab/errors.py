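"""Exception hierarchy shared across the package."""


class SnadError(Exception):
    """Base class for all snadlab errors."""


class DomainError(SnadError, ValueError):
    """An argument is outside its physically or mathematically valid domain."""


class InsufficientDataError(SnadError, ValueError):
    """Too few data points for the requested estimate."""


class DegenerateInputError(SnadError, ValueError):
    """Input is formally valid but carries no information (e.g. zero time variance)."""


class UndefinedRatioError(SnadError, ZeroDivisionError):
    """Denominator rate indistinguishable from zero; ratio undefined."""


class SaturationError(SnadError, ValueError):
    """Observed divergence at or beyond the saturation point of a distance model."""


class NoOverlapError(SnadError, ValueError):
    """No comparable alignment columns remain after pairwise deletion."""


class InvalidMatrixError(SnadError, ValueError):
    """Distance matrix is not symmetric, not finite, or otherwise malformed."""


class IncompleteCycleError(SnadError, ValueError):
    """A reactor-cycle phase required by a guard check is missing."""


class ConfigError(SnadError, ValueError):
    """A run configuration is invalid or references missing inputs."""
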