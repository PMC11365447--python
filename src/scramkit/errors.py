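"""Exception hierarchy for scramkit.

All scramkit-specific failures derive from :class:`ScramkitError` so callers
can catch the whole family with one clause.  Value-level problems additionally
derive from :class:`ValueError`.
"""


class ScramkitError(Exception):
    """Base class for all scramkit errors."""


class DomainError(ScramkitError, ValueError):
    """An input is outside the physically meaningful domain of an operation."""


class DegenerateBaselineError(DomainError):
    """The protein-free baseline consumes the full signal (e.g. 100% bleach),
    so the positive-vesicle fraction is undefined."""


class InfiniteOccupancyError(DomainError):
    """A positive-vesicle fraction of 1 implies an infinite Poisson mean."""


class InconsistentInputsError(DomainError):
    """Inputs combine to a physically impossible result (e.g. weight
    fraction above 1)."""


class InputError(ScramkitError, ValueError):
    """Malformed or insufficient input data (too few samples, all-zero
    lane, non-positive normalization constant, ...)."""


class WindowError(ScramkitError):
    """No qualifying reading window exists for the doubling-time rule."""


class NonGrowthError(ScramkitError):
    """The culture did not grow across the selected window (C2 <= C1)."""


class CalibrationError(ScramkitError):
    """The standard curve is unusable (e.g. non-positive slope)."""


class ConfigurationError(ScramkitError):
    """A simulation or pipeline configuration is invalid or incomplete."""
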