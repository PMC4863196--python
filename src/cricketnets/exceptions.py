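"""Exception and warning types shared across the package."""


class CricketNetsError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CricketNetsError):
    """A CSV input is missing a required column or has a malformed header."""


class ReferentialIntegrityError(CricketNetsError):
    """An event refers to an id that is absent from (or mis-sexed in) the roster."""


class LifespanViolationError(CricketNetsError):
    """An event falls outside a participant's adult lifespan (strict mode)."""


class LifespanViolationWarning(UserWarning):
    """An event falls outside a participant's adult lifespan (default mode)."""


class DegenerateInputError(CricketNetsError):
    """Input has no variation where a statistic requires it (constant matrix,
    all-zero paired differences, constant endpoint degrees, ...)."""


class RankDeficiencyError(CricketNetsError):
    """Predictor matrices are collinear; the offending pair is named."""


class AlignmentError(CricketNetsError):
    """Two labeled matrices do not share the same node set / ordering."""


class PipelineStageError(CricketNetsError):
    """A pipeline stage aborted; the message is prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
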