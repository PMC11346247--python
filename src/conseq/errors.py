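"""Exception types shared across the package."""


class ConseqError(Exception):
    """Base class for package errors."""


class ConfigurationError(ConseqError, ValueError):
    """A task or agent configuration is internally inconsistent."""


class StateError(ConseqError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class NumericalError(ConseqError, ArithmeticError):
    """Integration produced a non-finite state."""


class MetricUndefinedError(ConseqError, ValueError):
    """A behavioral metric is undefined for the given log (e.g. no qualifying trials)."""
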