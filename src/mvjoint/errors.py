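"""Exception hierarchy.

All package errors derive from :class:`MvJointError` so callers can catch
one base class; subclasses distinguish data-format problems from model
configuration and numerical-estimation failures.
"""


class MvJointError(Exception):
    """Base class for all mvjoint errors."""


class DataFormatError(MvJointError):
    """A delimited input file is missing required columns or is malformed."""


class ConsistencyError(MvJointError):
    """Longitudinal and survival tables disagree (e.g. unknown subject)."""


class ConfigError(MvJointError):
    """A model specification or simulation design is invalid."""


class DomainError(MvJointError, ValueError):
    """A numeric argument is outside its mathematical domain (σ ≤ 0, t ≤ 0, ...)."""


class EstimationError(MvJointError):
    """Model fitting failed in a way that cannot be reported as a result."""


class InitializationError(EstimationError):
    """Starting values could not be derived or give a non-finite likelihood."""


class UnsupportedDimensionError(MvJointError):
    """Full-likelihood fitting requested beyond the supported k ≤ 3."""
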