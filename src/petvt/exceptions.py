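"""Exception hierarchy.

``ValidationError`` (and its subclass ``InsufficientDataError``) signal bad
inputs; ``FitFailureError`` signals a model that could not be estimated.
The CLI maps these to exit codes 2 and 3 respectively.
"""


class PetvtError(Exception):
    """Base class for all package errors."""


class ValidationError(PetvtError):
    """Input violates a documented precondition or invariant."""


class InsufficientDataError(ValidationError):
    """Too few usable samples/frames for the requested fit."""


class FitFailureError(PetvtError):
    """An optimizer failed to converge.

    ``last_iterate`` carries the best parameter vector seen so far, when
    available, so callers can inspect where the fit stalled.
    """

    def __init__(self, message, last_iterate=None, diagnostics=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.diagnostics = diagnostics


class NoLinearPhaseError(FitFailureError):
    """No start time leaves enough points satisfying the linearity criterion."""


class PipelineStageError(PetvtError):
    """A pipeline stage failed; partial outputs are preserved on disk."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original
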