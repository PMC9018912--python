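"""Exception hierarchy for the betadose pipeline."""


class BetadoseError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(BetadoseError, ValueError):
    """An argument violates an operation's precondition."""


class FormatError(BetadoseError):
    """A session file violates the documented schema; message names the field."""


class CorruptFileError(BetadoseError):
    """A session file is schema-shaped but internally inconsistent."""


class AlignmentError(BetadoseError):
    """Accelerometer and LFP traces do not overlap sufficiently."""


class DegenerateInputError(BetadoseError, ValueError):
    """Input is degenerate for the requested computation (e.g. zero variance)."""


class CohortError(BetadoseError):
    """Cohort-level failure: no hemispheres survive quality control."""
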