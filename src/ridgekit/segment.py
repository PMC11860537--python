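"""Foreground segmentation of FTIR fingerprint captures.

The contact area of the fingertip appears as a bright, roughly elliptical
footprint on a dark background.  Thresholding the raw image fails because
ridge valleys inside the footprint are themselves dark, so the ridge-frequency
content is first suppressed with a normalized Gaussian blur (sigma = 50,
window = 99 by default) and the blurred image is binarized at the Otsu
threshold that maximizes the between-class variance.  A largest-component /
hole-filling cleanup enforces the expected single elliptical contact region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "GaussianKernel",
    "OtsuResult",
    "gaussian_kernel",
    "blur",
    "otsu_threshold",
    "make_mask",
]

DEFAULT_SIGMA = 50.0
DEFAULT_WINDOW = 99


@dataclass(frozen=True)
class GaussianKernel:
    """Normalized, truncated Gaussian kernel of odd ``window`` size.

    ``weights`` is the full 2-D kernel (sums to 1); ``weights_1d`` is the 1-D
    factor used for separable filtering (the 2-D kernel is its outer product).
    """

    sigma: float
    window: int
    weights: np.ndarray = field(repr=False)
    weights_1d: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class OtsuResult:
    """Otsu threshold with the class statistics realized at that threshold.

    The split convention is ``class 1 = {I < threshold}``,
    ``class 2 = {I >= threshold}`` on 8-bit (rounded) intensities.
    """

    threshold: int
    class_probs: tuple[float, float]
    class_means: tuple[float, float]
    criterion: float


def gaussian_kernel(sigma: float = DEFAULT_SIGMA, window: int = DEFAULT_WINDOW) -> GaussianKernel:
    """Build a normalized Gaussian kernel ``G(u,v) ∝ exp(-(u²+v²)/2σ²)``."""
    window = int(window)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"kernel window must be odd and >= 1, got {window}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = window // 2
    u = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-(u ** 2) / (2.0 * sigma ** 2))
    g1 /= g1.sum()
    g2 = np.outer(g1, g1)
    return GaussianKernel(sigma=float(sigma), window=window, weights=g2, weights_1d=g1)


def blur(img: np.ndarray, kernel: GaussianKernel) -> np.ndarray:
    """Convolve with a normalized Gaussian kernel, reflecting at the borders.

    Separability of the Gaussian is exploited (two 1-D passes); the result is
    identical to the direct 2-D weighted sum up to rounding.  A constant image
    maps to itself because the kernel is normalized.
    """
    arr = np.asarray(img, dtype=np.float64)
    out = ndimage.correlate1d(arr, kernel.weights_1d, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, kernel.weights_1d, axis=1, mode="reflect")
    return out


def _histogram_256(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of intensities after rounding to the 8-bit grid."""
    binned = np.clip(np.rint(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.intp)
    return np.bincount(binned.ravel(), minlength=256).astype(np.float64)


def otsu_threshold(img: np.ndarray) -> OtsuResult:
    """Exhaustive Otsu threshold on the 256-bin histogram.

    Scans every candidate threshold ``T`` in 1..255, maximizing the
    between-class variance ``ω₁ω₂(μ₁-μ₂)²`` of the split ``{I < T}`` vs
    ``{I >= T}`` (equivalent to minimizing the intra-class variance).  Ties
    resolve to the smallest optimal ``T`` for determinism.
    """
    hist = _histogram_256(img)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 distinct 8-bit levels")
    p = hist / total
    levels = np.arange(256, dtype=np.float64)
    # Cumulatives over class 1 = bins [0, T): evaluate at T = 1..255.
    w1 = np.cumsum(p)[:-1]                     # P(I < T), T = 1..255
    s1 = np.cumsum(p * levels)[:-1]            # E[I ; I < T]
    w2 = 1.0 - w1
    mu_total = float((p * levels).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        mu1 = np.where(w1 > 0, s1 / w1, 0.0)
        mu2 = np.where(w2 > 0, (mu_total - s1) / w2, 0.0)
    crit = w1 * w2 * (mu1 - mu2) ** 2
    t_star = int(np.argmax(crit)) + 1          # argmax returns the first (smallest) maximizer
    i = t_star - 1
    return OtsuResult(
        threshold=t_star,
        class_probs=(float(w1[i]), float(w2[i])),
        class_means=(float(mu1[i]), float(mu2[i])),
        criterion=float(crit[i]),
    )


def make_mask(
    img: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Segment the bright contact footprint; returns a boolean mask.

    Pipeline: Gaussian blur (suppresses ridge-frequency content) → Otsu
    binarization of the blurred image → keep the largest bright connected
    component → fill interior holes.

    Raises ``ValueError`` for a constant image or an empty foreground.
    """
    arr = np.asarray(img, dtype=np.float64)
    blurred = blur(arr, gaussian_kernel(sigma, window))
    result = otsu_threshold(blurred)
    binary = np.rint(blurred) >= result.threshold
    if not binary.any():
        raise ValueError("empty foreground after Otsu thresholding")
    labels = measure.label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background label
    largest = int(np.argmax(counts))
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    return mask
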