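"""Exception types shared across the pipeline."""


class CalfPlayError(Exception):
    """Base class for all package errors."""


class ConfigError(CalfPlayError):
    """A configuration value is missing, malformed or inconsistent."""


class InputError(CalfPlayError):
    """An input value violates a precondition (bad day number, dt <= 0, ...)."""


class SplitError(CalfPlayError):
    """Train/test partitioning is impossible (e.g. a single calf)."""


class DegenerateClassifierError(CalfPlayError):
    """The classifier's confusion rates make the adjusted count undefined
    (tpr <= fpr): the linear correction cannot be inverted."""


class InsufficientDataError(CalfPlayError):
    """A stage needs more data than the pool provides; the message names
    the shortfall."""


class FitConvergenceError(CalfPlayError):
    """A mixed-model fit failed to converge; carries optimiser diagnostics."""


class StageError(CalfPlayError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}:{code}] {message}")
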