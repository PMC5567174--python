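"""Exception hierarchy for flexitorque."""


class FlexitorqueError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FlexitorqueError, ValueError):
    """A parameter violates a documented constraint."""


class ProtocolError(FlexitorqueError, ValueError):
    """A trial protocol is invalid or does not match the requested operation."""


class InfeasibleProtocolError(ProtocolError):
    """An isotonic protocol whose impedance cannot be overcome across the ROM."""


class OutOfRangeError(FlexitorqueError, ValueError):
    """An angle lies outside the range of motion or a profile's support."""


class SegmentationError(FlexitorqueError, RuntimeError):
    """No usable flexion sweep could be identified in a trial."""


class CalibrationCoverageError(FlexitorqueError, RuntimeError):
    """Passive trials leave a coverage gap larger than the calibration bin."""


class RectificationError(FlexitorqueError, RuntimeError):
    """The circumference signal is too flat to be rectified."""


class InsufficientDataError(FlexitorqueError, RuntimeError):
    """Fewer valid samples than an operation requires."""


class DegenerateDataError(FlexitorqueError, RuntimeError):
    """Input data carry no usable variance or no valid samples."""


class TrainingError(FlexitorqueError, RuntimeError):
    """Curves supplied for training have no common valid angle range."""
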