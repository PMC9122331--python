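"""Exception hierarchy shared across the package.

CLI exit codes: 2 validation/configuration, 3 data/format, 4 numerical.
"""


class TurnoverError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(TurnoverError):
    """Invalid configuration value."""

    exit_code = 2


class FormatError(TurnoverError):
    """Malformed or incomplete input file."""

    exit_code = 3


class DataError(TurnoverError):
    """Input values violate a data contract (e.g. negative ratios)."""

    exit_code = 3


class FitError(TurnoverError):
    """A lifetime fit cannot be performed on the given time course."""

    exit_code = 4


class ComparisonError(TurnoverError):
    """Cross-cohort comparison precondition violated."""

    exit_code = 3


class NormalizationError(TurnoverError):
    """Abundance normalization impossible (e.g. all-zero sample column)."""

    exit_code = 4
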