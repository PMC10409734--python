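"""Exception types shared across the pipeline stages."""

from __future__ import annotations


class DetectionFailureError(RuntimeError):
    """A detection stage could not produce a result.

    Carries a ``stage`` name and a ``diagnostics`` mapping so that the
    pipeline can report which stage failed for which leg without guessing
    from the message text.
    """

    def __init__(self, message: str, stage: str = "", diagnostics: dict | None = None):
        super().__init__(message)
        self.stage = stage
        self.diagnostics = diagnostics or {}


class ModelTrainingError(ValueError):
    """Training data insufficient or degenerate for a statistical model."""


class TalusRotationWarning(UserWarning):
    """The segmented tibiotalar band deviates noticeably from horizontal.

    Detection on rotated ankles is unreliable; downstream results should be
    reviewed.
    """
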