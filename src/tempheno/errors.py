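"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`TemphenoError`, so callers can catch one type at the boundary.
Per-patient evaluation problems are wrapped in
:class:`PatientEvaluationError` by the pattern evaluator and turned into
per-patient ``error`` verdicts instead of aborting a whole cohort run.
"""

from __future__ import annotations


class TemphenoError(Exception):
    """Base class for all package errors."""


class FormatError(TemphenoError):
    """A file does not conform to the expected tabular layout."""


class RowError(FormatError):
    """A specific row could not be ingested.

    Carries the 1-based data row number so the offending line can be
    located in the source file.
    """

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class PreconditionError(TemphenoError):
    """An operation was called on inputs violating its contract."""


class UnitMismatchError(TemphenoError):
    """A condition's unit disagrees with an observation's unit.

    Units are opaque strings compared exactly; no conversion is ever
    attempted, because a silent mg/µg or °C/°F coercion is a patient
    safety hazard in a cohort definition.
    """


class ConfigError(TemphenoError):
    """An abstraction or relation specification is internally invalid."""


class SchemaError(ConfigError):
    """A declarative phenotype document violates the schema.

    ``path`` points at the offending node, e.g. ``pattern.and[1].rel``.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class VocabularyError(ConfigError):
    """An unknown relation, operator, aggregate or attribute name."""


class DomainError(TemphenoError):
    """A formula was evaluated outside its mathematical domain."""


class PatientEvaluationError(TemphenoError):
    """Evaluation failed for one patient (e.g. a missing external variable).

    The evaluator converts this into an ``error`` verdict for that
    patient; it never silently counts the patient as matched or
    unmatched.
    """

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)
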