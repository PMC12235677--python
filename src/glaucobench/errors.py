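"""Exception types shared across the package."""

from __future__ import annotations

from dataclasses import dataclass


class GlaucobenchError(Exception):
    """Base class for package errors."""


class ConfigurationError(GlaucobenchError):
    """A configuration (column mapping, filter, generator settings) is invalid."""


@dataclass(frozen=True)
class RowError:
    """One rejected input row: its 0-based data-row index and the reason."""

    row: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"data row {self.row}: {self.message}"


class CohortValidationError(GlaucobenchError):
    """Raised when tabular input rows fail validation; carries all row errors."""

    def __init__(self, errors):
        self.errors = list(errors)
        head = "; ".join(str(e) for e in self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} invalid row(s): {head}{more}")


class InsufficientDataError(GlaucobenchError):
    """Not enough observations to compute the requested quantity."""


class DegenerateDataError(GlaucobenchError):
    """The design is degenerate (e.g. all visits on one date)."""


class InconsistencyError(GlaucobenchError):
    """Derived counts would be negative or otherwise contradictory."""


class SchemaVersionError(GlaucobenchError):
    """Two benchmark reports use incompatible schema versions."""
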