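"""Exception hierarchy for the MR mediation pipeline."""


class MRMediateError(Exception):
    """Base class for all package errors."""


class MissingColumnError(MRMediateError):
    """A mandatory summary-statistics column is absent from the input file."""

    def __init__(self, column: str, path: str | None = None):
        self.column = column
        where = f" in {path}" if path else ""
        super().__init__(f"mandatory column {column!r} not found{where}")


class EmptyInputError(MRMediateError):
    """No valid records remain after validation."""


class LDValidationError(MRMediateError):
    """LD matrix violates symmetry / unit-diagonal / range invariants."""


class NoInstrumentsError(MRMediateError):
    """Instrument selection produced an empty set; MR cannot proceed."""


class InsufficientInstrumentsError(MRMediateError):
    """Fewer instruments than the estimator requires."""


class DegenerateInstrumentError(MRMediateError):
    """Wald ratio undefined (exposure effect is zero)."""


class UndefinedProportionError(MRMediateError):
    """Proportion mediated undefined (total effect is zero)."""


class NoQualifyingExposureError(MRMediateError):
    """No screened exposure passed both the forward and reverse filters."""
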