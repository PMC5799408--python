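"""Exception hierarchy for lickstruct.

Every error raised by the package derives from :class:`LickstructError` so
callers can catch pipeline failures at one level while still distinguishing
schema problems (bad files) from contract violations (bad arguments) and
design problems (unbalanced ANOVA layouts).
"""

from __future__ import annotations


class LickstructError(Exception):
    """Base class for all lickstruct errors."""


class SchemaError(LickstructError):
    """An input table is missing a required column or has the wrong layout."""


class ValidationError(LickstructError):
    """A value violates a domain invariant (negative timestamp, bad factor level...)."""


class ParseError(LickstructError):
    """A MED-PC (or other structured text) file could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ContractError(LickstructError):
    """A function precondition was violated (e.g. unsorted timestamps)."""


class DesignError(LickstructError):
    """An ANOVA design is unbalanced or has missing cells; such designs are
    rejected outright rather than approximated."""


class SeparationError(LickstructError):
    """Logistic regression data are completely separated; no finite MLE exists."""
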