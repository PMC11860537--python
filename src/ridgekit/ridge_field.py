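"""Block-wise ridge orientation and ridge spatial-frequency estimation.

Orientation is estimated from Sobel gradients with the classical doubled
angle (structure-tensor) averaging: per W x W block,

    V_x = sum 2 g_x g_y,   V_y = sum (g_x^2 - g_y^2),
    theta = 1/2 atan2(V_x, V_y)

which recovers the ridge-NORMAL angle (the direction of intensity
oscillation), folded into (-pi/2, pi/2].  The two-argument arctangent is used
because the single-argument form is undefined at ``V_y = 0`` and quadrant
ambiguous.  The field is regularized by blurring the doubled-angle vector
field (cos 2θ, sin 2θ) with a small Gaussian over the block grid.

Ridge spatial frequency per block is obtained by resampling a window around
the block center rotated so the ridge normal aligns with the row axis,
projecting row-wise to a 1-D profile P(i), locating the maxima via the sign
change of the forward difference K(i) = P(i+1) - P(i), dropping maxima closer
than a minimum peak distance (noise), and averaging the spacing of the
surviving maxima.  Blocks where fewer than two maxima survive, that fall
mostly outside the mask, or whose orientation coherence is too low carry the
value NaN ("invalid"); downstream stages skip them.

Angle convention: angles are measured from the +column (x) axis toward the
+row (y, downward) axis, in radians, and stored folded into (-pi/2, pi/2].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "OrientationField",
    "FrequencyField",
    "fold_angle",
    "sobel_gradients",
    "block_orientation",
    "smooth_orientation",
    "block_frequency",
    "regularize_frequency",
    "SOBEL_X",
    "SOBEL_Y",
    "DEFAULT_BLOCK",
]

DEFAULT_BLOCK = 40
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_SMOOTH_SIGMA = 1.0
DEFAULT_MIN_PEAK_DISTANCE = 4.0
MIN_COHERENCE = 0.1

#: 3x3 Sobel kernels (convolution kernels as conventionally printed).
SOBEL_X = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]], dtype=np.float64)
SOBEL_Y = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=np.float64)


def fold_angle(angle):
    """Fold angles (radians) into the half-open interval (-pi/2, pi/2]."""
    return np.pi / 2 - np.mod(np.pi / 2 - np.asarray(angle, dtype=np.float64), np.pi)


@dataclass(frozen=True)
class OrientationField:
    """Per-block ridge-normal angles with their coherence.

    ``theta`` is the raw block estimate; ``orientation`` is the smoothed map
    (equal to ``theta`` until :func:`smooth_orientation` is applied).
    ``coherence`` in [0, 1] measures how anisotropic the block gradients are.
    """

    block_size: int
    theta: np.ndarray = field(repr=False)
    coherence: np.ndarray = field(repr=False)
    orientation: np.ndarray = field(repr=False)
    smoothing_window: int | None = None

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.theta.shape


@dataclass(frozen=True)
class FrequencyField:
    """Per-block ridge period in pixels; NaN marks invalid blocks."""

    block_size: int
    period: np.ndarray = field(repr=False)
    min_peak_distance: float = DEFAULT_MIN_PEAK_DISTANCE

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.period)


def sobel_gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convolve with the 3x3 Sobel kernels (reflect borders).

    Returns ``(gx, gy)``: gradients along the column (x) and row (y, downward)
    axes respectively.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for Sobel gradients")
    gx = ndimage.convolve(arr, SOBEL_X, mode="reflect")
    gy = ndimage.convolve(arr, SOBEL_Y, mode="reflect")
    return gx, gy


def _block_sum(a: np.ndarray, W: int) -> np.ndarray:
    nb_r, nb_c = a.shape[0] // W, a.shape[1] // W
    trimmed = a[: nb_r * W, : nb_c * W]
    return trimmed.reshape(nb_r, W, nb_c, W).sum(axis=(1, 3))


def block_orientation(
    gx: np.ndarray, gy: np.ndarray, block_size: int = DEFAULT_BLOCK
) -> OrientationField:
    """Dominant ridge-normal angle per non-overlapping W x W block."""
    W = int(block_size)
    if gx.shape != gy.shape:
        raise ValueError("gradient images must share dimensions")
    if W > min(gx.shape):
        raise ValueError(f"block size {W} exceeds image dimensions {gx.shape}")
    vx = _block_sum(2.0 * gx * gy, W)
    vy = _block_sum(gx ** 2 - gy ** 2, W)
    denom = _block_sum(gx ** 2 + gy ** 2, W)
    theta = fold_angle(0.5 * np.arctan2(vx, vy))
    mag = np.hypot(vx, vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(denom > 0, mag / denom, 0.0)
    return OrientationField(block_size=W, theta=theta, coherence=coherence, orientation=theta)


def block_mask_fraction(mask: np.ndarray, block_size: int) -> np.ndarray:
    """Fraction of each block's pixels lying inside the foreground mask."""
    W = int(block_size)
    return _block_sum(np.asarray(mask, dtype=np.float64), W) / float(W * W)


def _grid_gaussian(window: int, sigma: float) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    half = window // 2
    u = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-(u ** 2) / (2.0 * sigma ** 2))
    return g / g.sum()


def smooth_orientation(
    fld: OrientationField,
    window: int = DEFAULT_SMOOTH_WINDOW,
    sigma: float = DEFAULT_SMOOTH_SIGMA,
    weights: np.ndarray | None = None,
) -> OrientationField:
    """Regularize the block orientation map in the doubled-angle domain.

    The raw angles are mapped to the continuous vector field
    ``(phi_x, phi_y) = (cos 2θ, sin 2θ)``, each component is blurred with a
    ``window x window`` Gaussian over the block grid (reflect borders), and
    the smoothed angle is recovered as ``O = 1/2 atan2(phi_y', phi_x')``.
    Working on doubled angles makes +89° and -89° near neighbors, so smoothing
    never averages across the ±pi/2 wrap.  The vectors are weighted by block
    coherence before blurring: a block whose gradients carry no directional
    information (background, flat regions) has coherence ~0 and therefore
    contributes nothing to its neighbors' smoothed angle.  ``weights``
    optionally multiplies that coherence weighting — the pipeline passes the
    per-block foreground fraction so that blocks straddling the footprint rim
    (whose gradients are dominated by the bright-to-dark boundary edge, not by
    ridges) do not contaminate their interior neighbors.
    """
    w = np.clip(fld.coherence, 0.0, 1.0)
    if weights is not None:
        w = w * np.clip(np.asarray(weights, dtype=np.float64), 0.0, 1.0)
    phi_x = w * np.cos(2.0 * fld.theta)
    phi_y = w * np.sin(2.0 * fld.theta)
    g = _grid_gaussian(window, sigma)
    for axis in (0, 1):
        phi_x = ndimage.correlate1d(phi_x, g, axis=axis, mode="reflect")
        phi_y = ndimage.correlate1d(phi_y, g, axis=axis, mode="reflect")
    smoothed = fold_angle(0.5 * np.arctan2(phi_y, phi_x))
    return replace(fld, orientation=smoothed, smoothing_window=int(window))


def _profile_maxima(profile: np.ndarray, min_distance: float) -> list[float]:
    """Maxima of a 1-D profile via the +→- sign change of the forward
    difference, with sub-pixel parabolic refinement and a minimum-spacing
    noise gate (a maximum too close to the previously kept one is dropped)."""
    K = np.diff(profile)
    kept: list[float] = []
    for i in range(1, len(K)):
        if K[i - 1] > 0 and K[i] <= 0:
            # 3-point parabolic refinement around the integer peak at i
            y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
            denom = y0 - 2 * y1 + y2
            offset = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            pos = i + float(np.clip(offset, -0.5, 0.5))
            if kept and pos - kept[-1] < min_distance:
                continue
            kept.append(pos)
    return kept


def block_frequency(
    img: np.ndarray,
    fld: OrientationField,
    mask: np.ndarray,
    min_peak_distance: float = DEFAULT_MIN_PEAK_DISTANCE,
    min_coherence: float = MIN_COHERENCE,
    min_mask_fraction: float = 0.5,
) -> FrequencyField:
    """Estimate the ridge period per block by rotation and row projection."""
    arr = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    W = fld.block_size
    nb_r, nb_c = fld.grid_shape
    period = np.full((nb_r, nb_c), np.nan)

    # Sampling offsets for a W x W window in the rotated frame.
    offs = np.arange(W, dtype=np.float64) - (W - 1) / 2.0
    di, dj = np.meshgrid(offs, offs, indexing="ij")

    mask_frac = _block_sum(mask.astype(np.float64), W) / float(W * W)
    H_img, W_img = arr.shape
    for bi in range(nb_r):
        for bj in range(nb_c):
            if mask_frac[bi, bj] < min_mask_fraction:
                continue
            if fld.coherence[bi, bj] < min_coherence:
                continue
            th = fld.orientation[bi, bj]
            cy = bi * W + (W - 1) / 2.0
            cx = bj * W + (W - 1) / 2.0
            # Rotate so the ridge normal maps onto the output row axis: the
            # output row direction i' samples along the normal (sin th, cos th)
            # and the column direction j' along the ridge (cos th, -sin th).
            rows = cy + di * np.sin(th) + dj * np.cos(th)
            cols = cx + di * np.cos(th) - dj * np.sin(th)
            window = ndimage.map_coordinates(
                arr, [rows, cols], order=1, mode="reflect"
            )
            profile = window.mean(axis=1)
            peaks = _profile_maxima(profile, min_peak_distance)
            if len(peaks) < 2:
                continue
            spacing = float(np.mean(np.diff(peaks)))
            if spacing >= min_peak_distance:
                period[bi, bj] = spacing
    return FrequencyField(block_size=W, period=period, min_peak_distance=float(min_peak_distance))


def _neighbor_median(lam: np.ndarray, bi: int, bj: int) -> float:
    nb = lam[max(bi - 1, 0) : bi + 2, max(bj - 1, 0) : bj + 2]
    vals = nb[np.isfinite(nb)]
    return float(np.median(vals)) if vals.size else np.nan


def regularize_frequency(
    freq: FrequencyField,
    mask_fraction: np.ndarray | None = None,
    smooth: bool = True,
    fill: bool = True,
) -> FrequencyField:
    """Median-regularize the block period map and fill isolated failures.

    Per-block period estimates are noisy where ridges are weak; a 3x3 median
    over valid neighbors suppresses outliers, and blocks whose own estimate
    failed inherit the median of their valid neighbors (iterated until no
    foreground block changes).  Blocks with no valid neighbor anywhere in
    their connected foreground neighborhood remain invalid.  ``mask_fraction``
    (per-block foreground fraction) restricts filling to blocks at least half
    inside the mask.
    """
    lam = freq.period.copy()
    nb_r, nb_c = lam.shape
    if smooth:
        smoothed = lam.copy()
        for bi in range(nb_r):
            for bj in range(nb_c):
                if np.isfinite(lam[bi, bj]):
                    smoothed[bi, bj] = _neighbor_median(lam, bi, bj)
        lam = smoothed
    if fill:
        fillable = np.ones_like(lam, dtype=bool) if mask_fraction is None else (
            np.asarray(mask_fraction) >= 0.5
        )
        for _ in range(max(nb_r, nb_c)):
            targets = fillable & ~np.isfinite(lam)
            if not targets.any():
                break
            new = lam.copy()
            changed = False
            for bi, bj in np.argwhere(targets):
                v = _neighbor_median(lam, bi, bj)
                if np.isfinite(v):
                    new[bi, bj] = v
                    changed = True
            lam = new
            if not changed:
                break
    return FrequencyField(
        block_size=freq.block_size, period=lam, min_peak_distance=freq.min_peak_distance
    )
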