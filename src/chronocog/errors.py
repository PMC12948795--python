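"""Exception hierarchy shared across the pipeline."""


class ChronocogError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ChronocogError, ValueError):
    """A configuration value is invalid; the message names the field."""


class ValidationError(ChronocogError, ValueError):
    """An input record violates its contract (range, completeness, join)."""


class GenerationError(ChronocogError, RuntimeError):
    """The synthetic generator was asked for something outside its span."""


class ExclusionError(ChronocogError, RuntimeError):
    """An operation was invoked on data that an upstream rule excludes."""


class UndefinedCircularMeanError(ChronocogError, ArithmeticError):
    """Circular mean requested for a fully dispersed set of clock times."""
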