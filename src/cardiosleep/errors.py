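"""Exception hierarchy for cardiosleep."""


class CardiosleepError(Exception):
    """Base class for all package errors."""


class ChannelNotFoundError(CardiosleepError, KeyError):
    """A named EDF channel is absent from the file."""


class FormatError(CardiosleepError, ValueError):
    """A file could not be parsed as the expected format."""


class GridError(CardiosleepError, ValueError):
    """Annotations do not fit the 30 s epoch grid of the recording."""


class VocabularyError(CardiosleepError, ValueError):
    """An unknown sleep-stage code was encountered."""


class ParameterError(CardiosleepError, ValueError):
    """An operation received an invalid parameter."""


class EmptyRecordingError(CardiosleepError, ValueError):
    """A recording retained no valid epochs."""


class DegenerateRecordingError(CardiosleepError, ValueError):
    """Recording statistics are degenerate (e.g. all epochs constant)."""


class CohortError(CardiosleepError, ValueError):
    """A cohort does not satisfy the requirements of a split or training run."""


class BalanceError(CardiosleepError, ValueError):
    """Batch balancing is impossible (a class is missing)."""


class ArchitectureError(CardiosleepError, ValueError):
    """A layer specification produces an invalid network."""


class ThresholdError(CardiosleepError, ValueError):
    """Confidence thresholds cannot be fitted (a predicted class is empty)."""
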