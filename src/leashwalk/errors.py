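"""Exception hierarchy for the leashwalk pipeline."""


class LeashwalkError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LeashwalkError):
    """A file does not conform to the expected dialect."""


class EmptyInputError(LeashwalkError):
    """An input file or array contained no usable data."""


class RangeError(LeashwalkError):
    """A value fell outside its physically or logically valid range."""


class ParameterError(LeashwalkError):
    """A configuration parameter is invalid."""


class ContractError(LeashwalkError):
    """A precondition of an operation was violated."""


class InsufficientDataError(LeashwalkError):
    """Too few samples or observations for the requested operation."""


class SyncFailureError(LeashwalkError):
    """The pre-walk synchronisation protocol could not be located.

    Carries the list of candidate pulses found so the caller can inspect
    why the expected count of three was not met.
    """

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = list(candidates) if candidates is not None else []


class CatalogError(LeashwalkError):
    """A behaviour is absent from, or inconsistent with, the ethogram catalog."""


class UndefinedStatisticError(LeashwalkError):
    """A statistic (e.g. Cronbach's alpha with zero variance) is undefined."""


class ScenarioError(LeashwalkError):
    """A synthetic-data scenario is internally inconsistent."""


class StageError(LeashwalkError):
    """A pipeline stage failed; carries the stage name and session id."""

    def __init__(self, stage: str, session_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for session {session_id!r}: {cause}")
        self.stage = stage
        self.session_id = session_id
        self.cause = cause
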