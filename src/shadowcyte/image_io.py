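"""Image and tabular I/O for shadow-smear pipelines.

All pixel data in the package flows through :class:`GrayImage`, an 8-bit
grayscale frame tagged with the physical pixel pitch of the sensor that
recorded it (1.67 µm for the contact-imaging CMOS sensor the defaults
assume). Color frames from the sensor are reduced to luma before any
segmentation, because the color rendition of a lens-free shadow image is
unreliable — only transmitted intensity carries signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import tifffile
from PIL import Image

#: ITU-R BT.601 luma weights (R, G, B).
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: Physical pixel pitch of the reference sensor, in µm.
DEFAULT_PIXEL_PITCH_UM = 1.67


class FormatError(ValueError):
    """Raised for images whose layout the pipeline does not accept."""


@dataclass
class GrayImage:
    """A 2-D 8-bit intensity grid with a physical pixel pitch.

    Parameters
    ----------
    pixels
        2-D array; stored as ``uint8`` (values 0–255).
    pixel_pitch
        Physical width of one pixel in µm. Must be positive.
    """

    pixels: np.ndarray
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise FormatError(f"GrayImage requires a 2-D array, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr
        if not self.pixel_pitch > 0:
            raise ValueError(f"pixel_pitch must be > 0, got {self.pixel_pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_grayscale(rgb: np.ndarray, weights: tuple[float, float, float] = BT601_WEIGHTS,
                 pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM) -> GrayImage:
    """Convert a 3-channel image to 8-bit luma.

    Uses the BT.601 weighted sum (configurable), rounded to the nearest
    integer and clipped to [0, 255]. Idempotent on images whose three
    channels are equal.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"expected a (rows, cols, 3) array, got shape {arr.shape}")
    w = np.asarray(weights, dtype=np.float64)
    luma = np.rint(arr @ w)
    return GrayImage(np.clip(luma, 0, 255).astype(np.uint8), pixel_pitch)


def _rescale_16bit(arr: np.ndarray) -> np.ndarray:
    # Fixed 65535 -> 255 ratio: deterministic, independent of image content.
    return np.rint(arr.astype(np.float64) * (255.0 / 65535.0)).astype(np.uint8)


def read_image(path: str | os.PathLike, pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM) -> GrayImage:
    """Read a PNG or TIFF smear image as 8-bit grayscale.

    16-bit input is rescaled by the fixed 65535→255 ratio; RGB input is
    converted via :func:`to_grayscale`. Other channel counts are rejected.
    """
    path = os.fspath(path)
    try:
        if path.lower().endswith((".tif", ".tiff")):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except (OSError, ValueError) as exc:
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc

    if arr.dtype == np.uint16:
        arr = _rescale_16bit(arr)
    elif arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)

    if arr.ndim == 2:
        return GrayImage(arr, pixel_pitch)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return to_grayscale(arr, pixel_pitch=pixel_pitch)
    raise FormatError(
        f"unsupported channel layout {arr.shape} in {path!r}: need 1 or 3 channels"
    )


def write_image(path: str | os.PathLike, img: GrayImage) -> None:
    """Write an 8-bit grayscale image as PNG or TIFF (by extension)."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, img.pixels)
    else:
        Image.fromarray(img.pixels, mode="L").save(path)
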