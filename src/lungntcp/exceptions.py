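"""Package-specific exception types."""


class LungNTCPError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LungNTCPError):
    """Invalid configuration (e.g. dose block outside the volume)."""


class SegmentationError(LungNTCPError):
    """Lung segmentation produced an empty mask."""

    def __init__(self, message, component_sizes_mm3=None):
        super().__init__(message)
        self.component_sizes_mm3 = component_sizes_mm3 or []


class RegistrationError(LungNTCPError):
    """Registration failed (e.g. insufficient overlap)."""


class EmptyOverlapError(LungNTCPError):
    """A resampling step left no valid voxels."""


class EmptyCurveError(LungNTCPError):
    """Dose binning found no usable pixels."""


class NoResponseError(LungNTCPError):
    """No positive HU change in any bin; nothing to normalize."""


class IncompatibleCurvesError(LungNTCPError):
    """Curves with mismatched bin edges cannot be pooled."""


class FitError(LungNTCPError):
    """Nonlinear least-squares fitting failed to converge."""
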