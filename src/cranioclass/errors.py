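"""Exception hierarchy.

Data/format problems map to CLI exit code 1, numerical failures
(divergence, unusable ensembles) to exit code 2.
"""


class CranioError(Exception):
    """Base class for all package errors."""


class DataFormatError(CranioError):
    """Malformed input table or configuration."""


class MissingColumnError(DataFormatError):
    """A required CSV column is absent."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(f"required column {column!r} is missing from the input")


class MeasurementParseError(DataFormatError):
    """A cell could not be parsed or violates positivity."""

    def __init__(self, row: int, column: str, reason: str):
        self.row = row
        self.column = column
        super().__init__(f"row {row}, column {column!r}: {reason}")


class StratificationError(DataFormatError):
    """A class has no records, so a stratified split is impossible."""


class DegenerateFeatureError(DataFormatError):
    """A feature is constant on the training rows (max == min)."""

    def __init__(self, feature: str):
        self.feature = feature
        super().__init__(
            f"feature {feature!r} is constant on the training rows; "
            "min-max normalization is undefined"
        )


class SpecError(DataFormatError):
    """An invalid synthetic-data specification."""


class NumericalError(CranioError):
    """Base class for runtime numerical failures (exit code 2)."""


class DivergenceError(NumericalError):
    """Training produced non-finite weights or error."""


class BoostAbortSignal(NumericalError):
    """A boosting round saw weighted error >= 0.5 (internal control flow)."""


class NoUsableLearnerError(NumericalError):
    """Every boosting round aborted; the ensemble is empty."""
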