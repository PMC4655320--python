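"""Exception types shared across the package."""


class PopScreenError(Exception):
    """Base class for errors raised by this package."""


class MissingInputError(PopScreenError):
    """A required measurement or field is absent."""


class DomainError(PopScreenError, ValueError):
    """An input violates a domain constraint (e.g. nonpositive biometry)."""


class RangeError(PopScreenError, ValueError):
    """A value falls outside the range covered by a reference standard."""


class FitError(PopScreenError):
    """A model fit failed (degenerate design, nonpositive SD curve, ...)."""


class CalibrationError(PopScreenError):
    """Requested cohort parameters are jointly infeasible."""


class ConfigurationError(PopScreenError):
    """A coefficient file or run configuration is missing or inconsistent."""


class ValidationError(PopScreenError):
    """Input tables violate the expected schema or internal consistency."""


class UndefinedMetricError(PopScreenError):
    """A diagnostic metric is undefined for the given table (zero margin)."""
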