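"""Exception hierarchy shared across the package."""


class VMREError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(VMREError):
    """Invalid simulation or pipeline configuration."""


class InputError(VMREError):
    """Malformed input volumes or tables (shape/affine mismatch, missing data)."""


class UnitError(VMREError):
    """A parametric map was passed with the wrong unit tag."""


class CalibrationError(VMREError):
    """Degenerate calibration parameters (e.g. zero slope)."""


class ValidationError(VMREError):
    """Protocol constraint violated (ROI slice coverage, non-positive values...)."""


class MeasurementError(VMREError):
    """No usable voxels/values to measure."""


class QCError(VMREError):
    """Quality-control quantity undefined (e.g. non-positive median)."""


class AnalysisError(VMREError):
    """A statistical routine received data it cannot analyze."""
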