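"""Exception hierarchy shared across the pipeline."""


class AcoustocalibError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(AcoustocalibError, ValueError):
    """Input data or configuration violates a documented invariant."""


class SegmentationError(AcoustocalibError, RuntimeError):
    """A frame failed quality control during area segmentation."""


class CalibrationRangeError(AcoustocalibError, ValueError):
    """A deformability slope falls outside the calibrated knot range."""
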