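"""Exception hierarchy shared across the package."""


class CfmrdError(Exception):
    """Base class for all package errors."""


class SchemaError(CfmrdError):
    """An input table is missing required columns or has a malformed header."""


class DataError(CfmrdError):
    """Row-level validation failure (bad values, duplicate keys, inconsistent days)."""


class ConfigError(CfmrdError):
    """Invalid run or simulation configuration."""


class NotEvaluable(CfmrdError):
    """The requested quantity cannot be computed from the available data.

    Mirrors the "NE" state used in clinical reporting: too few informative
    SNPs, too few timepoints, all-zero paired differences, and similar.
    """
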