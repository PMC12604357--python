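"""Exception hierarchy for welfareopt."""


class WelfareOptError(Exception):
    """Base class for all welfareopt errors."""


class SchemaError(WelfareOptError):
    """A required column is missing or the file cannot be parsed."""


class DataValidationError(WelfareOptError):
    """A cell value violates the data model (bad ordinal, blank label,
    conflicting metadata for one entity, empty input)."""


class UnknownEntityError(WelfareOptError, KeyError):
    """A species, class, indicator or weight-factor label was not found."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return Exception.__str__(self)


class CapacityError(WelfareOptError):
    """An exhaustive operation was asked for more items than its 2^n guard
    permits."""


class SyntheticSpecError(WelfareOptError):
    """A synthetic-database specification is infeasible."""
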