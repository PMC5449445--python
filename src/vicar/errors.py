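"""Exception hierarchy for the registration pipeline."""


class VicarError(Exception):
    """Base class for all package errors."""


class ValidationError(VicarError, ValueError):
    """Input violates a documented precondition (shape, dtype, config value)."""


class FrameIOError(VicarError, IOError):
    """A frame file could not be read or written."""


class PreprocessError(VicarError):
    """A preprocessing stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"preprocess stage '{stage}': {message}")


class DegenerateGeometryError(VicarError):
    """Geometry too degenerate to use (collinear control points, singular transform)."""


class NoCuesError(VicarError):
    """A frame exposes no visual cues; it cannot anchor a registration."""


class ShiftTooLargeError(VicarError):
    """Cue displacement between frames exceeds half the image width.

    Beyond that shift there is no guarantee the cues found in the first
    frame are still inside the visual field, so matching is refused.
    """


class UnregistrableSeriesError(VicarError):
    """No consecutive frame pair in the series can be registered."""


class BaselineFailureError(VicarError):
    """The Hough-transform baseline found too few line features in a frame.

    This is the documented failure mode of the baseline on scenes without
    straight structural edges; it is raised, not papered over.
    """

    def __init__(self, t: int, message: str = "no lines detected"):
        self.t = t
        super().__init__(f"frame {t}: {message}")
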