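"""Typed exceptions shared across the pipeline.

Every stage raises a subclass of :class:`BnWhatIfError` so callers (and the
CLI) can distinguish validation problems from genuine runtime failures.
"""


class BnWhatIfError(Exception):
    """Base class for all package errors."""


# --- network construction / inference -------------------------------------

class IncompleteAssignmentError(BnWhatIfError):
    """A full joint assignment is missing at least one variable."""


class UnknownStateError(BnWhatIfError):
    """A state label is not legal for its variable."""


class UnknownNodeError(BnWhatIfError):
    """A referenced variable does not exist in the network."""


class InvalidQueryError(BnWhatIfError):
    """The query variable is itself part of the evidence."""


class InconsistentEvidenceError(BnWhatIfError):
    """The evidence has probability zero under the network."""


class TooLargeError(BnWhatIfError):
    """The joint state space exceeds the brute-force enumeration guard."""


class InvalidSizeError(BnWhatIfError):
    """A sample size or count argument is out of range."""


# --- learning --------------------------------------------------------------

class UncleanDataError(BnWhatIfError):
    """Learning data still contains missing values or unknown states."""


class DegenerateInputError(BnWhatIfError):
    """The dataset has too few columns to learn a structure from."""


# --- preprocessing ---------------------------------------------------------

class InvalidAnthropometryError(BnWhatIfError):
    """Non-positive weight or height."""


class OutOfChartError(BnWhatIfError):
    """(age, sex) outside the growth chart's coverage."""


class MergeTypeError(BnWhatIfError):
    """An attribute-merge source column is not ordinal-coded."""


class InvalidDurationError(BnWhatIfError):
    """A negative minutes-per-day value."""


# --- sensitivity / what-if -------------------------------------------------

class DegenerateTargetError(BnWhatIfError):
    """The target node has zero entropy; entropy percentages are undefined."""


# --- synthetic data --------------------------------------------------------

class InvalidCorruptionError(BnWhatIfError):
    """Corruption rates are out of range or sum to one or more."""


class IncomparableNetworksError(BnWhatIfError):
    """Two networks do not share the same variable roster."""


# --- evaluation ------------------------------------------------------------

class StratificationError(BnWhatIfError):
    """A class is too rare for the requested number of stratified folds."""


class AUCUndefinedError(BnWhatIfError):
    """Fewer than two classes observed; ranking AUC is undefined."""


# --- configuration ---------------------------------------------------------

class ConfigError(BnWhatIfError):
    """Invalid or incomplete pipeline configuration."""
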