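"""Exception types shared across the pipeline."""


class CoexsurvError(ValueError):
    """Base class for all validation and analysis errors in this package."""


class ValidationError(CoexsurvError):
    """Malformed or inconsistent input data (bad ids, non-numeric cells, ...)."""


class ZeroVarianceError(CoexsurvError):
    """A correlation was requested on a constant vector."""


class StageError(CoexsurvError):
    """A pipeline stage failed; the message carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage {stage}] {message}")
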