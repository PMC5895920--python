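"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`AdAuditError`, so
callers (including the CLI) can distinguish data problems from bugs.
"""


class AdAuditError(Exception):
    """Base class for all adaudit errors."""


class InvalidArgumentError(AdAuditError, ValueError):
    """A parameter violates its documented precondition."""


class ValidationError(AdAuditError, ValueError):
    """Structured input (snapshot, table, taxonomy, config) fails validation."""


class MissingEstimateError(AdAuditError, KeyError):
    """An audience query is absent from the snapshot it was looked up in."""


class MissingInterestError(AdAuditError, KeyError):
    """A query names an interest the audience universe does not know."""


class DegenerateInputError(AdAuditError, ValueError):
    """A statistic is undefined for the input (e.g. constant vector)."""


class UndefinedShareError(AdAuditError, ZeroDivisionError):
    """A normalized share has a zero reference count in its denominator."""


class UndefinedLiftError(AdAuditError, ZeroDivisionError):
    """A lift is undefined because a marginal or base count is zero."""


class InconsistentCountsError(AdAuditError, ValueError):
    """A joint audience count exceeds a marginal beyond rounding slack."""


class CollinearityError(AdAuditError, ValueError):
    """A regression design matrix is rank deficient."""


class ConfigurationError(AdAuditError, ValueError):
    """An analysis configuration is unusable (e.g. no placebo interests)."""
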