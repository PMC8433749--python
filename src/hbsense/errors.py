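"""Exception types shared across the package."""


class HbSenseError(Exception):
    """Base class for all package-specific errors."""


class CalibrationError(HbSenseError):
    """Raised when a calibration is invalid or cannot be fitted."""


class CorruptFrameError(HbSenseError):
    """Raised when a sensor reading is physically impossible
    (e.g. non-positive transmitted intensity after offset correction)."""


class UnusableFrameError(HbSenseError):
    """Raised when a frame carries no usable illumination
    (LED off, tube blocked, sensor mispositioned)."""


class NoValidROIError(HbSenseError):
    """Raised when no artifact-free measurement region of sufficient
    width exists; the sensor must be repositioned on the tube."""
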