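"""Exception types shared across the pipeline stages."""


class ValidationError(ValueError):
    """An input violates a stated precondition (bad proportion, wrong arity, ...)."""


class FitError(RuntimeError):
    """A model fit failed (non-convergence, degenerate data)."""


class SeparationError(FitError):
    """Complete or quasi-complete separation detected during a logistic fit."""

    def __init__(self, message: str, predictors=None):
        super().__init__(message)
        self.predictors = tuple(predictors or ())


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for error reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
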