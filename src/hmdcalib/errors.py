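"""Exception hierarchy shared across the calibration and evaluation pipeline."""


class HmdCalibError(Exception):
    """Base class for all package-specific failures."""


class BehindCameraError(HmdCalibError):
    """A point has non-positive depth in the camera frame and cannot be projected."""


class InsufficientCorrespondencesError(HmdCalibError):
    """Fewer than three point pairs were supplied to the rigid solver."""


class DegenerateConfigurationError(HmdCalibError):
    """Source points are collinear or the cross-covariance is rank deficient."""


class IncompleteSessionError(HmdCalibError):
    """The observation stream ended before the target pair count was reached."""


class InsufficientMarkersError(HmdCalibError):
    """Fewer than two fiducial markers of the configuration were detected."""


class RegistrationFailedError(HmdCalibError):
    """Scan alignment quality exceeded the acceptance threshold."""


class FiducialsNotFoundError(HmdCalibError):
    """The four corner square-markers could not be located in a scan."""


class PointCountMismatchError(HmdCalibError):
    """Blob detection found a different number of points than expected."""

    def __init__(self, found: int, expected: int):
        self.found = found
        self.expected = expected
        super().__init__(f"found {found} points, expected {expected}")


class EmptyContourError(HmdCalibError):
    """A contour polyline with no vertices was supplied."""


class CountMismatchError(HmdCalibError):
    """Fiducial point lists of unequal length were supplied to the FRE."""


class InvalidBaselineError(HmdCalibError):
    """Percent improvement requested against a non-positive baseline."""


class NoPairsError(HmdCalibError):
    """TRE requested on an empty point-match result."""


class DegenerateSampleError(HmdCalibError):
    """A constant sample was supplied to the normality test."""


class InsufficientGroupsError(HmdCalibError):
    """Fewer than two groups were supplied to the omnibus comparison."""


class InvalidSubscaleError(HmdCalibError):
    """A NASA-TLX subscale score lies outside [0, 100]."""


class GenerationFailedError(HmdCalibError):
    """Phantom generation could not satisfy the spacing constraints."""
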