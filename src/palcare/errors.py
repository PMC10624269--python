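"""Exception hierarchy for the palcare pipeline.

Every error raised by the library derives from :class:`PalcareError`, so
callers (and the CLI) can separate validation problems (exit code 2) from
I/O problems (exit code 3).
"""

from __future__ import annotations


class PalcareError(Exception):
    """Base class for all palcare errors."""


class ScenarioIOError(PalcareError):
    """A scenario file or output path could not be read or written."""


class ScenarioValidationError(PalcareError):
    """An input table violates a scenario invariant.

    Parameters
    ----------
    message:
        Human-readable description.
    table, row, field:
        Optional context naming the offending CSV table, row index and
        column, included in ``str(error)`` when present.
    """

    def __init__(self, message: str, *, table: str | None = None,
                 row: int | None = None, field: str | None = None) -> None:
        self.table = table
        self.row = row
        self.field = field
        ctx = [p for p in (
            f"table={table}" if table else None,
            f"row={row}" if row is not None else None,
            f"field={field}" if field else None,
        ) if p]
        super().__init__(message + (f" [{', '.join(ctx)}]" if ctx else ""))


class NoDataError(PalcareError):
    """The country record is flagged as having no data."""


class ZeroNeedError(PalcareError):
    """An operation requiring at least one patient in need got zero."""


class ZeroBurdenError(PalcareError):
    """Symptom shares requested for a country with zero symptom days."""


class ZeroRequirementError(PalcareError):
    """Percent of need met requested with a zero opioid requirement."""


class MissingStageError(PalcareError):
    """A figure export was requested for a pipeline stage that did not run."""
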