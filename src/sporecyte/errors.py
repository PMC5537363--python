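"""Named exceptions raised across the package."""


class SporecyteError(Exception):
    """Base class for all package-specific errors."""


class ImageNotFoundError(SporecyteError, FileNotFoundError):
    """The requested image file does not exist."""


class InvalidPixelSizeError(SporecyteError, ValueError):
    """A pixel-size calibration was zero, negative or non-finite."""


class RasterDecodeError(SporecyteError, ValueError):
    """The file exists but could not be decoded as a raster image."""


class DegenerateImageError(SporecyteError, ValueError):
    """Automatic thresholding was asked for on a constant image."""


class GeometryMismatchError(SporecyteError, ValueError):
    """Two images/masks that must share geometry (shape, pixel size) do not."""


class CalibrationError(SporecyteError, ValueError):
    """Too few particles (or otherwise unusable data) to calibrate from."""


class PackingError(SporecyteError, RuntimeError):
    """The synthetic scene could not place all requested objects."""
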