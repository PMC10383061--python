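"""Exception hierarchy for strip analysis failures.

Detection errors signal an unreadable or invalid strip rather than a bug;
the batch pipeline catches :class:`StripAnalysisError` per image and reports
the failure without aborting the run.
"""


class LFIAError(Exception):
    """Base class for all package errors."""


class StripAnalysisError(LFIAError):
    """A strip image could not be analyzed (invalid or blank strip)."""


class ImageTooSmallError(StripAnalysisError):
    """Input image is below the minimum usable size (20 x 40 px)."""


class NotLandscapeError(StripAnalysisError):
    """Image is not a landscape strip (width < 2 x height) after orientation."""


class ControlLineNotFoundError(StripAnalysisError):
    """No column run below the control threshold qualifies as a control line."""


class ControlLineLostError(StripAnalysisError):
    """The control line region disappeared during list refinement."""


class EmptyLineRegionError(StripAnalysisError):
    """A line region has zero area; signals cannot be read from it."""


class InvalidControlSignalError(StripAnalysisError):
    """Control signal C <= 0; features are undefined for this strip."""


class InsufficientCalibrationDataError(LFIAError):
    """Too few (feature, concentration) pairs to fit a calibration curve."""


class DegenerateResponseError(LFIAError):
    """All observed responses identical; R-squared is undefined (SS_tot = 0)."""
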