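"""Exception hierarchy for aslcomp."""


class AslCompError(Exception):
    """Base class for all aslcomp errors."""


class InvalidBolusError(AslCompError):
    """Raised when a bolus duration is non-positive."""


class InvalidDispersionError(AslCompError):
    """Raised when a dispersion width is negative."""


class UnusableTraceError(AslCompError):
    """Raised when a physiological trace yields fewer than two systolic peaks."""


class OutOfTraceError(AslCompError):
    """Raised when an acquisition timestamp falls outside the peak-covered interval."""


class CalibrationError(AslCompError):
    """Raised when M0 calibration is attempted with an empty CSF mask."""


class InvalidPressureError(AslCompError):
    """Raised when pulse pressure is non-positive."""
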