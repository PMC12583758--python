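"""Exception hierarchy shared across the pipeline.

Errors are split by *who* has to fix them: configuration (bad factor file,
unknown GWP set), format (malformed CSV), validation (data violates an
invariant such as a negative head count), and domain (a quantity is outside
the mathematical domain of an operation, e.g. a non-positive base-year value
in a growth rate).
"""


class LivecarbonError(Exception):
    """Base class for all package errors."""


class ConfigError(LivecarbonError):
    """Invalid run or factor configuration."""


class FormatError(LivecarbonError):
    """A file does not conform to its documented schema."""


class ValidationError(LivecarbonError):
    """Data violates a structural invariant."""


class DomainError(LivecarbonError):
    """A value lies outside the mathematical domain of an operation."""
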