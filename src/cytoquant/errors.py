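"""Exception and warning taxonomy shared across the package.

Errors signal contract violations; warnings flag recoverable oddities
(empty segmentations, degenerate cells, orphan CSVs) that the CLI also
collects into the run manifest.
"""


class CytoquantError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(CytoquantError):
    """File is not a readable TIFF / CSV, or its layout cannot be interpreted."""


class ChannelLimitError(CytoquantError):
    """Image carries more channels than the supported maximum (5)."""


class CalibrationMissingError(CytoquantError):
    """No pixel size given and none recoverable from TIFF metadata."""


class CalibrationError(CytoquantError):
    """Pixel calibration is unusable (non-positive or anisotropic in-plane)."""


class ConfigurationError(CytoquantError):
    """Invalid option value, method name, or classification config."""


class RoiInvalidError(CytoquantError):
    """Region-of-interest polygon is degenerate or self-intersecting."""


class BackendUnavailableError(CytoquantError):
    """Requested segmentation backend cannot be imported."""


class MissingLabelError(CytoquantError, KeyError):
    """A label id was requested that does not exist."""


class PairingError(CytoquantError):
    """Without/with-enlargement tables or files cannot be paired."""


class DataIntegrityError(CytoquantError):
    """Measurement tables are internally inconsistent (e.g. negative ring mean)."""


class DomainError(CytoquantError, ValueError):
    """Scalar argument outside its mathematical domain."""


class PackingInfeasibleError(CytoquantError):
    """Rejection sampler could not place the requested number of nuclei."""

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class EmptySegmentationWarning(UserWarning):
    """Segmentation produced zero labels."""


class EmptyRegionWarning(UserWarning):
    """A measured region has no pixels; intensities are NaN sentinels."""


class DegenerateCellWarning(UserWarning):
    """Expanded area equals nucleus area; ring mean falls back to nucleus mean."""


class UnpairedFileWarning(UserWarning):
    """A measurement CSV has no enlargement partner and was skipped."""
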