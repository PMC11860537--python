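"""Local brightness-error correction and mean/variance normalization.

Uneven contact pressure and light/tissue interaction leave smooth, low
frequency brightness errors across the fingerprint footprint.  The masked
image is modeled as ``I_masked = r + b_real`` where ``r`` is the
high-frequency ridge component and ``b_real = b_ideal + e`` is the realistic
background including the error field ``e``.  ``b_real`` is estimated by
Gaussian blur of the masked image (mask-normalized so the estimate stays
unbiased near the footprint edge), subtracted to isolate ``r``, and the mean
background level is added back so the corrected image keeps a natural
brightness:

    corrected = (I_masked - b_real) + mean(b_real over foreground)

Normalization then maps the corrected foreground to a fixed target mean m0
and variance v0 (both 100 by default):

    I_norm = m0 + sqrt(v0 (I - m)^2 / v)   if I >= m
             m0 - sqrt(v0 (I - m)^2 / v)   if I <  m

which is the affine map ``m0 + (I - m) sqrt(v0 / v)``; the foreground of the
result has mean m0 and (population) variance v0 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segment import gaussian_kernel, blur, DEFAULT_SIGMA, DEFAULT_WINDOW

__all__ = [
    "BrightnessDecomposition",
    "apply_mask",
    "estimate_background",
    "correct_brightness",
    "normalize",
    "DEFAULT_TARGET_MEAN",
    "DEFAULT_TARGET_VAR",
]

DEFAULT_TARGET_MEAN = 100.0
DEFAULT_TARGET_VAR = 100.0


@dataclass(frozen=True)
class BrightnessDecomposition:
    """Decomposition of a masked image into ridge and background terms.

    Invariants (exact up to float rounding, asserted by the test suite):
    ``masked == ridge + background_real`` on the foreground, and
    ``corrected == ridge + background_mean`` on the foreground.
    """

    masked: np.ndarray = field(repr=False)
    ridge: np.ndarray = field(repr=False)
    background_real: np.ndarray = field(repr=False)
    background_mean: float = 0.0
    corrected: np.ndarray = field(repr=False, default=None)


def apply_mask(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero everything outside the foreground mask."""
    arr = np.asarray(img, dtype=np.float64)
    return np.where(mask, arr, 0.0)


def estimate_background(
    masked: np.ndarray,
    mask: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Estimate the smooth background component of a masked image.

    A plain Gaussian blur would bleed the zeroed background across the mask
    edge and bias the estimate exactly where pressure errors concentrate, so
    the blur is mask-normalized: ``blur(I·mask) / blur(mask)``, evaluated on
    the foreground (zero elsewhere).  For a ridge-free constant foreground the
    estimate is exactly that constant.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty foreground mask")
    kernel = gaussian_kernel(sigma, window)
    num = blur(apply_mask(masked, mask), kernel)
    den = blur(mask.astype(np.float64), kernel)
    bg = np.zeros_like(num)
    inside = mask & (den > 1e-12)
    bg[inside] = num[inside] / den[inside]
    return bg


def correct_brightness(
    masked: np.ndarray,
    mask: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    window: int = DEFAULT_WINDOW,
) -> BrightnessDecomposition:
    """Remove the local brightness-error field from a masked image.

    Returns the full decomposition; ``corrected`` is the flattened image
    (ridge component plus the foreground-mean background level), zero outside
    the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    masked = apply_mask(masked, mask)
    b_real = estimate_background(masked, mask, sigma=sigma, window=window)
    ridge = np.where(mask, masked - b_real, 0.0)
    b_mean = float(b_real[mask].mean())
    corrected = np.where(mask, ridge + b_mean, 0.0)
    return BrightnessDecomposition(
        masked=masked,
        ridge=ridge,
        background_real=b_real,
        background_mean=b_mean,
        corrected=corrected,
    )


def normalize(
    corrected: np.ndarray,
    mask: np.ndarray,
    target_mean: float = DEFAULT_TARGET_MEAN,
    target_var: float = DEFAULT_TARGET_VAR,
) -> np.ndarray:
    """Normalize foreground intensities to a fixed mean and variance.

    ``m`` and ``v`` are computed over the foreground only (the zeroed
    background would otherwise dominate both).  Background pixels are set to
    ``target_mean`` so the mask boundary carries no artificial gradient into
    the downstream Sobel stage.
    """
    mask = np.asarray(mask, dtype=bool)
    arr = np.asarray(corrected, dtype=np.float64)
    if not mask.any():
        raise ValueError("empty foreground mask")
    fg = arr[mask]
    m = float(fg.mean())
    v = float(fg.var())  # population variance; the target is hit exactly
    if v <= 0:
        raise ValueError("flat foreground: variance is zero, cannot normalize")
    dev = arr - m
    scaled = np.sqrt(target_var * dev ** 2 / v)
    out = np.where(dev >= 0, target_mean + scaled, target_mean - scaled)
    return np.where(mask, out, target_mean)
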