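"""Exception hierarchy and process exit codes.

Exit codes are part of the CLI contract: schema problems (malformed input
files), domain problems (physically invalid values), and configuration
problems each map to a distinct nonzero code so shell pipelines can branch
on the failure class.
"""


class LiftRiskError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(LiftRiskError):
    """An input file or record violates its declared schema."""

    exit_code = 3


class DomainError(LiftRiskError, ValueError):
    """A value is outside the physical/mathematical domain of an operation."""

    exit_code = 4


class UndefinedComparisonError(DomainError):
    """A percent change was requested against a zero reference."""


class ConfigError(LiftRiskError):
    """A run configuration is malformed or inconsistent."""

    exit_code = 5
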