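"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class BoundsError(ParameterError):
    """A requested window or schedule falls outside the recording."""


class UndefinedResultError(ArithmeticError):
    """A quantity is mathematically undefined for the given input
    (e.g. a fatigue-index denominator that is not positive)."""


class FormatError(ValueError):
    """A file does not conform to the trace/report format."""


class ConfigError(ValueError):
    """A run configuration contains unknown or invalid entries."""
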