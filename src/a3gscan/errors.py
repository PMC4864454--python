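"""Exception hierarchy.

Validation problems (bad configuration, malformed files, out-of-domain
arguments) are distinguished from runtime failures so the command-line
driver can map them to distinct exit codes.
"""


class A3GScanError(Exception):
    """Base class for package errors."""


class ValidationError(A3GScanError, ValueError):
    """User input is invalid (configuration, arguments, file format)."""


class ConfigError(ValidationError):
    """A configuration field is invalid; message names the field."""


class FormatError(ValidationError):
    """A file does not conform to its declared format."""


class ArgumentError(ValidationError):
    """An argument violates a documented domain restriction."""


class ConsistencyError(A3GScanError):
    """Inputs that must agree (e.g. allele tracks vs mutations) do not."""


class UndefinedStatisticError(A3GScanError):
    """A ratio or correlation is undefined on the given data (empty
    denominator, zero variance)."""


class InsufficientMotifsError(A3GScanError):
    """The genome does not contain enough motif sites to place the
    requested number of cluster events."""
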