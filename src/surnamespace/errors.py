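"""Exception hierarchy for surname-space analysis."""


class SurnameSpaceError(Exception):
    """Base class for all package errors."""


class SchemaError(SurnameSpaceError):
    """Input data violates the expected schema (missing columns, duplicates)."""


class ValidationError(SurnameSpaceError):
    """Data values violate an invariant (non-positive counts, bad thresholds)."""


class MappingError(SurnameSpaceError):
    """A region-aggregation mapping does not cover the data."""


class LookupError_(SurnameSpaceError, KeyError):
    """A surname or region is not present in the object queried."""


class UndefinedStatisticError(SurnameSpaceError):
    """A statistic is mathematically undefined for the given input."""


class ConfigError(SurnameSpaceError):
    """A pipeline run configuration is invalid or incomplete."""
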