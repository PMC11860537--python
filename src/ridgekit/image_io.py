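"""Raster image reading/writing, channel selection and region-of-interest cropping.

Conventions used throughout the package
---------------------------------------
* A grayscale image ("GrayImage") is a 2-D ``float64`` :class:`numpy.ndarray`
  indexed ``[row, column]``, 0-based, row 0 at the top.  Intensities live on
  the 8-bit scale ``[0, 255]`` but are kept real-valued internally;
  quantization to ``uint8`` happens only when an image is written to disk.
* A color image ("ColorImage") is an ``(H, W, 3)`` ``float64`` array in
  R, G, B channel order.
* Sizes are reported ``width x height`` (so the default region of interest is
  1200 x 800 even though the corresponding array has shape ``(800, 1200)``).

FTIR captures place the fingerprint contact area as a bright elliptical
footprint on a dark background; ridges are the bright phase.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "read_image",
    "write_image",
    "to_grayscale_average",
    "select_channel",
    "extract_roi",
    "DEFAULT_ROI_SIZE",
]

#: Default region-of-interest size as (width, height) in pixels.
DEFAULT_ROI_SIZE = (1200, 800)

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2}


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as float64.

    Returns an ``(H, W)`` array for grayscale files and an ``(H, W, 3)``
    array for RGB files (an alpha channel, if present, is dropped).
    """
    with Image.open(path) as im:
        if im.mode in ("RGB", "RGBA"):
            arr = np.asarray(im.convert("RGB"), dtype=np.float64)
        else:
            arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr


def write_image(path, img: np.ndarray) -> None:
    """Write an image to disk, quantizing to 8 bits (round then clip)."""
    arr = np.asarray(img, dtype=np.float64)
    q = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(q).save(path)


def _require_color(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) color image, got shape {arr.shape}")
    return arr


def to_grayscale_average(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to grayscale as the per-pixel channel average.

    ``I(i,j) = (I_R + I_G + I_B) / 3`` — the plain average keeps all three
    channels' contributions and is therefore *not* suitable for studying a
    single illumination wavelength; see :func:`select_channel` for that.
    """
    arr = _require_color(img)
    return arr.mean(axis=2)


def select_channel(img: np.ndarray, light: str) -> np.ndarray:
    """Return the single color channel matching the illumination label.

    When a capture is taken under narrow-band R, G or B illumination only the
    matching sensor channel carries the signal of interest, so the channel is
    extracted untouched instead of averaging.

    Parameters
    ----------
    light:
        One of ``"R"``, ``"G"``, ``"B"`` (case-insensitive).
    """
    arr = _require_color(img)
    key = str(light).upper()
    if key not in _CHANNEL_INDEX:
        raise ValueError(f"unknown illumination label {light!r}; expected R, G or B")
    return arr[:, :, _CHANNEL_INDEX[key]].copy()


def _auto_center(img: np.ndarray, blur_sigma: float = 25.0) -> tuple[float, float]:
    """Intensity centroid of the blurred image, as (row, col)."""
    blurred = ndimage.gaussian_filter(img, blur_sigma, mode="reflect")
    total = blurred.sum()
    if total <= 0:
        # All-dark image: fall back to the geometric center.
        return ((img.shape[0] - 1) / 2.0, (img.shape[1] - 1) / 2.0)
    rows = np.arange(img.shape[0], dtype=np.float64)
    cols = np.arange(img.shape[1], dtype=np.float64)
    r = float((blurred.sum(axis=1) * rows).sum() / total)
    c = float((blurred.sum(axis=0) * cols).sum() / total)
    return (r, c)


def extract_roi(
    img: np.ndarray,
    center: tuple[float, float] | str | None = "auto",
    size: tuple[int, int] = DEFAULT_ROI_SIZE,
) -> np.ndarray:
    """Crop a contiguous region of interest around the fingerprint.

    Parameters
    ----------
    img:
        2-D grayscale array.
    center:
        ``(row, col)`` of the ROI center, or ``"auto"``/``None`` to center on
        the intensity centroid of a blurred copy (the contact footprint is the
        dominant bright structure, so its centroid is a robust anchor).  An
        automatically chosen center is clamped so the ROI stays in bounds.
    size:
        ``(width, height)`` of the crop; defaults to 1200 x 800.

    Raises
    ------
    ValueError
        If an explicitly requested ROI extends past the image bounds; the
        message names the overflowing side(s).
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("extract_roi expects a 2-D grayscale image")
    w, h = int(size[0]), int(size[1])
    H, W = arr.shape
    if w > W or h > H:
        raise ValueError(f"ROI {w}x{h} larger than image {W}x{H}")

    auto = center is None or (isinstance(center, str) and center == "auto")
    if auto:
        cr, cc = _auto_center(arr)
    else:
        cr, cc = float(center[0]), float(center[1])

    top = int(round(cr - h / 2.0))
    left = int(round(cc - w / 2.0))
    if auto:
        top = min(max(top, 0), H - h)
        left = min(max(left, 0), W - w)
    else:
        overflow = []
        if top < 0:
            overflow.append("top")
        if left < 0:
            overflow.append("left")
        if top + h > H:
            overflow.append("bottom")
        if left + w > W:
            overflow.append("right")
        if overflow:
            raise ValueError(f"ROI exceeds image bounds on side(s): {', '.join(overflow)}")
    return arr[top : top + h, left : left + w].copy()
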