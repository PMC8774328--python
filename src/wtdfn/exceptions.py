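"""Package-wide error types."""


class WTDFNError(Exception):
    """Base class for package errors."""


class ConfigError(WTDFNError, ValueError):
    """A configuration value is out of range or names an unknown component."""


class InvalidInputError(WTDFNError, ValueError):
    """An input array violates a precondition (shape, finiteness, range)."""


class UndefinedMetricError(WTDFNError, ValueError):
    """A metric is undefined for the given inputs (e.g. AUC with one class)."""
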