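"""Exception hierarchy for ctpa_yield.

Validation is total: every malformed input produces a typed error naming the
offending row/field/key; nothing is silently dropped.
"""


class CTPAYieldError(Exception):
    """Base class for all ctpa_yield errors."""


class SchemaError(CTPAYieldError):
    """A table is missing a required column."""


class RowValidationError(CTPAYieldError):
    """A row failed validation; carries the 1-based data-row number and field."""

    def __init__(self, row: int, field: str, message: str):
        self.row = row
        self.field = field
        super().__init__(f"row {row}, field '{field}': {message}")


class IntegrityError(CTPAYieldError):
    """A referential or uniqueness constraint is violated."""


class UndefinedStatisticError(CTPAYieldError):
    """A statistic is undefined for the given table (e.g. degenerate marginals)."""


class InfeasibleSpecError(CTPAYieldError):
    """A synthetic cohort spec requests impossible counts."""
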