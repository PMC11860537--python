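"""Serialization and simple visual overlays for block fields."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .ridge_field import OrientationField, FrequencyField

__all__ = ["write_fields", "orientation_overlay"]


def write_fields(out_dir, fld: OrientationField, freq: FrequencyField) -> None:
    """Write ``orientation.csv`` and ``lambda.csv`` block grids.

    Orientation is in radians; invalid frequency cells are left empty.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "orientation.csv", fld.orientation, delimiter=",", fmt="%.6f")
    lam = freq.period
    with open(out / "lambda.csv", "w") as fh:
        for row in lam:
            fh.write(",".join("" if not np.isfinite(v) else f"{v:.3f}" for v in row) + "\n")


def orientation_overlay(img: np.ndarray, fld: OrientationField) -> Image.Image:
    """Draw per-block ridge-direction strokes over the image.

    The stored angle is the ridge normal; the stroke drawn is its
    perpendicular, i.e. the direction the ridges actually run.
    """
    base = np.clip(np.rint(np.asarray(img, dtype=np.float64)), 0, 255).astype(np.uint8)
    im = Image.fromarray(base).convert("RGB")
    draw = ImageDraw.Draw(im)
    W = fld.block_size
    L = 0.4 * W
    for bi in range(fld.grid_shape[0]):
        for bj in range(fld.grid_shape[1]):
            th = fld.orientation[bi, bj] + np.pi / 2.0  # ridge direction
            cy = bi * W + W / 2.0
            cx = bj * W + W / 2.0
            dy, dx = L * np.sin(th), L * np.cos(th)
            draw.line([(cx - dx, cy - dy), (cx + dx, cy + dy)], fill=(255, 255, 255), width=1)
    return im
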