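"""Exception hierarchy shared across the package."""


class CoughspotError(Exception):
    """Base class for all package errors."""


class InputError(CoughspotError):
    """Malformed or out-of-contract input data."""


class DegenerateInputError(InputError):
    """Structurally valid input that is empty or otherwise unusable."""


class ConfigurationError(CoughspotError):
    """Inconsistent configuration, e.g. an untrained or mismatched network."""


class NumericError(CoughspotError):
    """Numerical failure (divergence, non-finite likelihood)."""


class UndefinedMetricError(CoughspotError):
    """A statistic whose preconditions (variance, counts) are violated."""
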