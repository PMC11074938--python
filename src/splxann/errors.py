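"""Exception hierarchy for splxann.

Every stage raises a subclass of :class:`SplxannError` so that pipeline
orchestration can abort with the offending stage name while callers that
want fine-grained handling can catch the specific class.
"""


class SplxannError(Exception):
    """Base class for all package errors."""


class ConfigError(SplxannError):
    """A configuration object violates one of its invariants."""


class TableValidationError(SplxannError):
    """An observation table violates the table contract."""


class ParseError(TableValidationError):
    """A delimited-text table could not be parsed into a valid table."""


class EstimationError(SplxannError):
    """A parameter-estimator cell could not be fitted (e.g. n < 2)."""


class SplitError(SplxannError):
    """A train/validation split is impossible (e.g. a class with < 2 animals)."""


class TrainingError(SplxannError):
    """Network training received an unusable training set."""


class PredictionError(SplxannError):
    """Prediction inputs do not match the trained ensemble's feature set."""


class UndefinedAccuracyError(SplxannError):
    """Class-conditional accuracy requested for a class with zero records."""


class UndefinedStatisticError(SplxannError):
    """A test statistic is undefined for the given data (e.g. zero variance)."""


class IncompleteGridError(SplxannError):
    """A grid summary was requested on an incomplete ablation grid."""


class ResumeError(SplxannError):
    """A grid checkpoint exists but cannot be reused."""
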