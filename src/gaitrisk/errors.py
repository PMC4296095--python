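"""Package-wide exception types."""


class InvalidParameterError(ValueError):
    """A parameter object violates its invariants."""


class ConfigurationError(ValueError):
    """A configuration references unknown fields or is internally inconsistent."""


class PerfectSeparationError(RuntimeError):
    """The logistic likelihood is unbounded (perfectly separable data)."""
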