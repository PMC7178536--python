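"""Exception hierarchy shared across the pipeline stages."""


class QAMSError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(QAMSError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateFitError(QAMSError):
    """A regression cannot be fitted (e.g. zero concentration variance)."""


class PairingError(QAMSError):
    """Two dilution series cannot be paired level by level."""


class ZeroResponseError(QAMSError, ZeroDivisionError):
    """A zero area, concentration, slope or response ratio where a division
    is required; the message names the offending level or quantity."""


class PeakLocationError(QAMSError):
    """Peak assignment failed (e.g. no peak near the reference position)."""


class DecompositionError(QAMSError):
    """A correlation matrix is not positive semi-definite."""


class UndefinedStatisticError(QAMSError):
    """A statistic is undefined for the given data (e.g. RSD of zero-mean
    values, correlation of a constant column)."""


class SchemaError(QAMSError):
    """A tabular file is missing a required column."""


class TableParseError(QAMSError):
    """A tabular file contains a cell that cannot be parsed; the message
    carries the row number."""


class ConfigError(QAMSError):
    """A pipeline configuration is internally inconsistent."""
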