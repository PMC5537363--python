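"""Reading and writing calibrated fluorescence micrographs.

A micrograph on its own carries no physical scale; everything downstream
(areas in μm², the cluster-corrected count) depends on the μm-per-pixel
calibration, so the calibration travels with the pixels in a single
:class:`FluorImage` value. Intensities are kept exactly as stored on disk —
no rescaling, no normalisation — because thresholding is responsible for
handling dynamic range.
"""

from __future__ import annotations

import enum
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ImageNotFoundError, InvalidPixelSizeError, RasterDecodeError

__all__ = [
    "Channel",
    "FluorImage",
    "load_image",
    "save_image",
    "infer_pixel_size",
]


class Channel(str, enum.Enum):
    """Which fluorescence signal an image carries."""

    CHLOROPHYLL = "chlorophyll"  # intrinsic ~685 nm autofluorescence of spores
    CY5 = "cy5"  # amine-reactive label on adhesive-pad protein
    OTHER = "other"


#: How to reduce an RGB raster to the single analysed channel.
RGB_MODES = ("red", "green", "blue", "mean")


@dataclass(frozen=True)
class FluorImage:
    """A single-channel fluorescence micrograph with physical calibration.

    Parameters
    ----------
    pixels:
        2-D array of non-negative, finite intensities. Integer inputs keep
        their dtype so that saving round-trips bit-exactly.
    pixel_size_um:
        Physical edge length of one (square) pixel in micrometres.
    channel:
        Which signal the image carries (chlorophyll autofluorescence for
        spore bodies, Cy5 for adhesive pads).
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: Channel = Channel.OTHER
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {px.shape}")
        if not np.isfinite(px).all():
            raise ValueError("image contains non-finite intensities")
        if (px < 0).any():
            raise ValueError("image contains negative intensities")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise InvalidPixelSizeError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def physical_width_um(self) -> float:
        return self.width * self.pixel_size_um

    @property
    def physical_height_um(self) -> float:
        return self.height * self.pixel_size_um

    @property
    def field_area_um2(self) -> float:
        return self.physical_width_um * self.physical_height_um


def _reduce_rgb(arr: np.ndarray, rgb_mode: str) -> np.ndarray:
    if rgb_mode not in RGB_MODES:
        raise ValueError(f"rgb_mode must be one of {RGB_MODES}, got {rgb_mode!r}")
    if rgb_mode == "mean":
        return arr[..., :3].mean(axis=-1)
    return arr[..., RGB_MODES.index(rgb_mode)]


def load_image(
    path: str | os.PathLike,
    pixel_size_um: float,
    channel: Channel | str = Channel.OTHER,
    rgb_mode: str = "red",
) -> FluorImage:
    """Load a grayscale (or RGB) TIFF/PNG micrograph with its calibration.

    8- and 16-bit integer images are returned without rescaling. RGB rasters
    are reduced to one channel: the default is the red channel, which is
    where chlorophyll autofluorescence (~685 nm) renders in colour
    micrographs; pass ``rgb_mode="mean"`` for a luminance average.

    Raises
    ------
    ImageNotFoundError
        If ``path`` does not exist.
    InvalidPixelSizeError
        If ``pixel_size_um`` is not a positive finite number.
    RasterDecodeError
        If the file cannot be decoded as a raster image.
    """
    if not (np.isfinite(pixel_size_um) and pixel_size_um > 0):
        raise InvalidPixelSizeError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    if not os.path.exists(path):
        raise ImageNotFoundError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises a zoo of backend errors
        raise RasterDecodeError(f"could not decode {path} as a raster image: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[-1] not in (3, 4):
            raise RasterDecodeError(
                f"{path}: expected grayscale or RGB(A), got shape {arr.shape}"
            )
        arr = _reduce_rgb(arr, rgb_mode)
    elif arr.ndim != 2:
        raise RasterDecodeError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    return FluorImage(arr, pixel_size_um, Channel(channel), source_path=str(path))


def save_image(image: FluorImage, path: str | os.PathLike) -> None:
    """Write a micrograph losslessly (TIFF via tifffile, PNG via imageio).

    Float pixel data is saved as 16-bit after rounding, since neither format
    carries float grayscale portably; integer data keeps its dtype.
    """
    px = image.pixels
    if not np.issubdtype(px.dtype, np.integer):
        px = np.clip(np.rint(px), 0, 65535).astype(np.uint16)
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)


def infer_pixel_size(width_px: int, field_width_um: float) -> float:
    """Pixel size (μm) from a known physical field width.

    Microscope metadata is often unavailable, but the physical field of view
    usually is (e.g. a 2.4 mm-wide field imaged at 1600 px gives 1.5 μm/px).
    """
    if width_px <= 0:
        raise ValueError(f"width_px must be positive, got {width_px}")
    if not (np.isfinite(field_width_um) and field_width_um > 0):
        raise ValueError(f"field_width_um must be positive, got {field_width_um}")
    return field_width_um / width_px
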