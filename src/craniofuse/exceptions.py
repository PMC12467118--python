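"""Typed error signals raised across the registration pipeline."""


class CraniofuseError(Exception):
    """Base class for all package-specific errors."""


class EmptyCloudError(CraniofuseError, ValueError):
    """A point cloud with zero points was passed where geometry is required."""


class InvalidInputError(CraniofuseError, ValueError):
    """A precondition on user input was violated (non-finite values, bad shape...)."""


class FaceNotInViewError(CraniofuseError):
    """No point of the cloud projects inside the virtual camera frame."""


class LandmarkDepthMissingError(CraniofuseError):
    """No rendered depth available near a landmark pixel."""


class DetectionFailureError(CraniofuseError):
    """The landmark provider could not detect a face on the current view."""


class DegenerateGeometryError(CraniofuseError):
    """Correspondence geometry is rank-deficient; a rigid transform cannot be estimated."""


class ZeroInlierError(CraniofuseError):
    """No inlier correspondences: the inlier RMSE is undefined (not zero)."""


class RegistrationFailedError(CraniofuseError):
    """The registration pipeline could not produce a usable alignment."""
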