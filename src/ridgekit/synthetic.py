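"""Synthetic FTIR fingerprint images with exact ground truth.

No public FTIR fingerprint dataset accompanies the pipeline, so every
downstream stage is exercised on synthetic captures that emulate the
characteristic degradations of real FTIR imaging: a bright elliptical contact
footprint on a dark background, locally sinusoidal ridge texture (ridge
crests bright, valleys dark), a smooth low-frequency brightness-error field
from uneven contact pressure, additive pixel noise, and condition-dependent
contrast.

The ridge texture is generated from an analytic phase map rather than by
filtering noise: each orientation model corresponds to a closed-form "ridge
coordinate" u(i, j) whose gradient direction is known exactly, so the
generator can emit the true orientation field, ridge period and minutiae
alongside the image.  Ridge endings/bifurcations are induced by adding phase
dislocations (2π winding terms) at random interior positions, and the
ground-truth minutiae are defined operationally by skeletonizing the clean,
noiseless pattern and applying the crossing-number rule — the same geometric
definition the detector uses, evaluated on the undegraded signal.

Orientation models
------------------
``("constant", angle)``
    Parallel ridges; the ridge-normal angle is ``angle`` everywhere.
``("linear", theta_min, theta_max)``
    Concentric circular ridges around a far-away center, giving a normal
    angle that sweeps smoothly (approximately linearly) from ``theta_min`` to
    ``theta_max`` across the image; the period is exact everywhere.
``("core",)`` or ``("core", row, col)``
    A loop-type singularity (nested parabolic ridges): the doubled angle
    winds by exactly 2π around the core.  The local period varies as
    sqrt(r / r_ref) away from the reference radius.

All randomness flows from ``spec.seed`` through named ``numpy`` generator
substreams; identical specs give bit-identical outputs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import image_io
from .minutiae import Minutia, extract_minutiae
from .ridge_field import fold_angle
from skimage.morphology import skeletonize

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_orientation_field",
    "render_ridge_image",
    "degrade",
    "emit_condition_set",
    "CONDITION_PRESETS",
    "CHANNEL_MODIFIERS",
    "parse_orientation_model",
]

BACKGROUND_LEVEL = 30.0
BASE_LEVEL = 140.0
RIDGE_AMPLITUDE = 60.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic FTIR capture.

    ``footprint`` is ``(center_row, center_col, semi_axis_row, semi_axis_col)``
    in pixels; ``None`` centers an ellipse covering ~84% of each dimension.
    ``contrast`` scales the ridge modulation (0 = no ridges, 1 = full).
    """

    width: int = 1200
    height: int = 800
    ridge_period: float = 8.0
    orientation_model: tuple = ("constant", 0.3)
    footprint: tuple[float, float, float, float] | None = None
    contrast: float = 0.7
    brightness_error_amplitude: float = 20.0
    brightness_error_scale: float = 200.0
    noise_sd: float = 8.0
    n_dislocations: int = 10
    seed: int = 0

    def resolved_footprint(self) -> tuple[float, float, float, float]:
        if self.footprint is not None:
            return self.footprint
        return (
            (self.height - 1) / 2.0,
            (self.width - 1) / 2.0,
            0.42 * self.height,
            0.42 * self.width,
        )

    def validate(self) -> None:
        if self.ridge_period < 4:
            raise ValueError("ridge_period must be >= 4 px (sampling limit)")
        if self.width < 8 or self.height < 8:
            raise ValueError("image too small")
        cr, cc, ar, ac = self.resolved_footprint()
        if cr - ar < -0.5 or cr + ar > self.height - 0.5 or cc - ac < -0.5 or cc + ac > self.width - 0.5:
            raise ValueError("footprint ellipse extends beyond the image bounds")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless render plus everything the estimators should recover."""

    clean_image: np.ndarray = field(repr=False)
    orientation: np.ndarray = field(repr=False)
    period: float = 0.0
    footprint_mask: np.ndarray = field(repr=False, default=None)
    minutiae: list[Minutia] = field(default_factory=list)


def parse_orientation_model(text: str) -> tuple:
    """Parse CLI strings like ``constant:0.3``, ``linear:-0.5:0.5``, ``core``."""
    parts = str(text).split(":")
    name = parts[0]
    args = tuple(float(p) for p in parts[1:])
    if name == "constant":
        return ("constant", args[0] if args else 0.0)
    if name == "linear":
        if len(args) != 2:
            raise ValueError("linear model needs two angles: linear:MIN:MAX")
        return ("linear", args[0], args[1])
    if name == "core":
        return ("core",) + args
    raise ValueError(f"unknown orientation model {name!r}")


def _model_geometry(spec: SyntheticSpec):
    """Resolve per-model geometric constants shared by field and phase."""
    model = spec.orientation_model
    name = model[0]
    H, W = spec.height, spec.width
    if name == "constant":
        return ("constant", float(model[1]))
    if name == "linear":
        t0, t1 = float(model[1]), float(model[2])
        mid = 0.5 * (t0 + t1)
        half = 0.5 * abs(t1 - t0)
        if half < 1e-9:
            return ("constant", mid)
        dist = 0.5 * max(W, H) / np.tan(half)
        cy = (H - 1) / 2.0 - dist * np.sin(mid)
        cx = (W - 1) / 2.0 - dist * np.cos(mid)
        return ("linear", cy, cx)
    if name == "core":
        if len(model) >= 3:
            cy, cx = float(model[1]), float(model[2])
        else:
            cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
        _, _, ar, ac = spec.resolved_footprint()
        r_ref = 0.5 * min(ar, ac)
        return ("core", cy, cx, r_ref)
    raise ValueError(f"unknown orientation model {name!r}")


def _grid(spec: SyntheticSpec):
    i = np.arange(spec.height, dtype=np.float64)[:, None]
    j = np.arange(spec.width, dtype=np.float64)[None, :]
    return i, j


def make_orientation_field(spec: SyntheticSpec) -> np.ndarray:
    """Dense ridge-normal angle grid in (-pi/2, pi/2] for the spec's model.

    The returned field is exactly the gradient direction of the base phase
    map used by :func:`render_ridge_image` (before phase dislocations).
    """
    spec.validate()
    geo = _model_geometry(spec)
    i, j = _grid(spec)
    if geo[0] == "constant":
        return np.full((spec.height, spec.width), fold_angle(geo[1]))
    if geo[0] == "linear":
        _, cy, cx = geo
        return fold_angle(np.arctan2(i - cy, j - cx)) * np.ones((spec.height, spec.width))
    # core: half-winding singularity
    _, cy, cx, _ = geo
    return fold_angle(0.5 * np.arctan2(i - cy, j - cx)) * np.ones((spec.height, spec.width))


def _base_phase_gradient(spec: SyntheticSpec):
    """Phase map of the ridge pattern and its analytic gradient.

    Returns ``(phase, d_phase/d_row, d_phase/d_col)``.  The gradient magnitude
    of the base phase equals 2π/period for the constant and linear models
    (exact period everywhere).
    """
    geo = _model_geometry(spec)
    i, j = _grid(spec)
    k = 2.0 * np.pi / spec.ridge_period
    if geo[0] == "constant":
        alpha = geo[1]
        phase = k * (j * np.cos(alpha) + i * np.sin(alpha))
        gr = np.full_like(phase, k * np.sin(alpha))
        gc = np.full_like(phase, k * np.cos(alpha))
        return phase, gr, gc
    if geo[0] == "linear":
        _, cy, cx = geo
        di, dj = i - cy, j - cx
        r = np.hypot(di, dj)
        r = np.maximum(r, 1e-9)
        phase = k * r
        return phase, k * di / r, k * dj / r
    # core: u = sqrt(2 r_ref (r + dx)) — confocal parabolas about the core,
    # normal direction = half the polar angle.
    _, cy, cx, r_ref = geo
    di, dj = i - cy, j - cx
    r = np.hypot(di, dj)
    u2 = np.maximum(2.0 * r_ref * (r + dj), 1e-6)
    u = np.sqrt(u2)
    phase = k * u
    rr = np.maximum(r, 1e-9)
    du_dr_row = r_ref * (di / rr) / u
    du_dr_col = r_ref * (dj / rr + 1.0) / u
    return phase, k * du_dr_row, k * du_dr_col


def _dislocation_positions(spec: SyntheticSpec, margin: float = 40.0) -> np.ndarray:
    """Random interior positions for phase dislocations (one per minutia)."""
    if spec.n_dislocations <= 0:
        return np.empty((0, 2))
    rng = np.random.default_rng([spec.seed, 101])
    cr, cc, ar, ac = spec.resolved_footprint()
    pts = []
    # Rejection-sample inside the shrunken footprint ellipse.
    shrink_r = max(ar - margin, 1.0)
    shrink_c = max(ac - margin, 1.0)
    while len(pts) < spec.n_dislocations:
        u = rng.uniform(-1, 1, size=2)
        if u[0] ** 2 + u[1] ** 2 <= 1.0:
            pts.append((cr + u[0] * shrink_r, cc + u[1] * shrink_c))
    return np.array(pts)


def _footprint_mask(spec: SyntheticSpec) -> np.ndarray:
    cr, cc, ar, ac = spec.resolved_footprint()
    i, j = _grid(spec)
    return ((i - cr) / ar) ** 2 + ((j - cc) / ac) ** 2 <= 1.0


def render_ridge_image(spec: SyntheticSpec, field_grid: np.ndarray | None = None) -> GroundTruth:
    """Render the clean (noiseless) capture and derive its ground truth.

    ``field_grid`` is accepted for API symmetry but the render always uses the
    analytic phase of ``spec.orientation_model`` so that the recorded
    orientation truth (the exact gradient direction of the total phase,
    including dislocation terms) matches the image perfectly.
    """
    spec.validate()
    phase, gr, gc = _base_phase_gradient(spec)
    if spec.n_dislocations > 0 and spec.contrast > 0:
        i, j = _grid(spec)
        for (pr, pc) in _dislocation_positions(spec):
            di, dj = i - pr, j - pc
            r2 = np.maximum(di ** 2 + dj ** 2, 1e-9)
            phase = phase + np.arctan2(di, dj)
            gr = gr + dj / r2
            gc = gc - di / r2
    orientation = fold_angle(np.arctan2(gr, gc))

    mask = _footprint_mask(spec)
    signal = spec.contrast * RIDGE_AMPLITUDE * np.sin(phase)
    clean = np.where(mask, BASE_LEVEL + signal, BACKGROUND_LEVEL)
    clean = np.clip(clean, 0.0, 255.0)

    minutiae: list[Minutia] = []
    if spec.contrast > 0:
        binary = mask & (np.sin(phase) > 0)
        skel = skeletonize(binary)
        if skel.any():
            minutiae = extract_minutiae(skel, mask)
    return GroundTruth(
        clean_image=clean,
        orientation=orientation,
        period=float(spec.ridge_period),
        footprint_mask=mask,
        minutiae=minutiae,
    )


def degrade(truth: GroundTruth, spec: SyntheticSpec) -> np.ndarray:
    """Add the low-frequency brightness-error field and pixel noise.

    The error field is white noise blurred at ``brightness_error_scale`` and
    rescaled so its absolute peak equals ``brightness_error_amplitude``.
    Ground-truth minutiae always refer to the clean pattern and are untouched.
    """
    spec.validate()
    if truth.clean_image.shape != (spec.height, spec.width):
        raise ValueError("ground truth and spec dimensions disagree")
    out = truth.clean_image.astype(np.float64).copy()
    if spec.brightness_error_amplitude > 0:
        rng = np.random.default_rng([spec.seed, 202])
        noise = rng.standard_normal(out.shape)
        lowf = ndimage.gaussian_filter(noise, spec.brightness_error_scale / 4.0, mode="reflect")
        peak = np.abs(lowf).max()
        if peak > 0:
            out += lowf / peak * spec.brightness_error_amplitude
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 303])
        out += rng.normal(0.0, spec.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 255.0)


# Moisture presets: wet contact (WC) couples the skin to the plate best and
# yields the cleanest, highest-contrast captures; the untreated control (UC)
# is intermediate; dry skin (DC) couples poorly — lower contrast, more noise
# and stronger pressure-related brightness errors.  Channel modifiers encode
# that longer (R) wavelengths penetrate deeper into skin, diffusing the ridge
# signal, while G/B stay near the surface.  These presets are illustrative
# operating points, not a calibrated optical model.
CONDITION_PRESETS: dict[str, dict] = {
    "WC": {"contrast": 0.9, "noise_sd": 6.0, "brightness_error_amplitude": 15.0},
    "UC": {"contrast": 0.65, "noise_sd": 10.0, "brightness_error_amplitude": 22.0},
    "DC": {"contrast": 0.45, "noise_sd": 14.0, "brightness_error_amplitude": 30.0},
}

CHANNEL_MODIFIERS: dict[str, dict] = {
    "R": {"contrast_mul": 0.75, "noise_mul": 1.25},
    "G": {"contrast_mul": 1.0, "noise_mul": 1.0},
    "B": {"contrast_mul": 1.05, "noise_mul": 0.95},
}


def _preset_for_label(label: str) -> dict:
    """Resolve a condition label ('WC', 'DC-R', ...) to degradation settings."""
    parts = label.split("-")
    settings: dict = {}
    contrast_mul = 1.0
    noise_mul = 1.0
    for p in parts:
        if p in CONDITION_PRESETS:
            settings.update(CONDITION_PRESETS[p])
        elif p in CHANNEL_MODIFIERS:
            contrast_mul *= CHANNEL_MODIFIERS[p]["contrast_mul"]
            noise_mul *= CHANNEL_MODIFIERS[p]["noise_mul"]
        else:
            raise ValueError(f"unknown condition label component {p!r} in {label!r}")
    if "contrast" in settings:
        settings["contrast"] = min(1.0, settings["contrast"] * contrast_mul)
    if "noise_sd" in settings:
        settings["noise_sd"] = settings["noise_sd"] * noise_mul
    return settings


def emit_condition_set(
    base_spec: SyntheticSpec,
    conditions: list[str],
    out_dir: str | Path | None = None,
) -> dict[str, tuple[np.ndarray, GroundTruth]]:
    """Render one degraded capture per condition label, sharing geometry.

    All labels share the clean pattern of ``base_spec`` (same footprint,
    ridge geometry and truth minutiae); each label only changes the
    contrast/noise/brightness-error settings per its preset and uses its own
    noise substream.  Optionally writes one 8-bit PNG per label plus the
    shared ground-truth minutiae CSV (header ``x,y,type,quality``).
    """
    if len(set(conditions)) != len(conditions):
        raise ValueError("duplicate condition labels")
    results: dict[str, tuple[np.ndarray, GroundTruth]] = {}
    if not conditions:
        return results
    for idx, label in enumerate(conditions):
        settings = _preset_for_label(label)
        spec = replace(base_spec, seed=int(base_spec.seed) * 1000 + idx, **settings)
        # Geometry/truth comes from the *base* spec's pattern: render with the
        # label's contrast but the base seed so dislocations are shared.
        spec_render = replace(spec, seed=base_spec.seed)
        truth = render_ridge_image(spec_render)
        degraded = degrade(truth, replace(spec, seed=int(base_spec.seed) * 1000 + idx))
        results[label] = (degraded, truth)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, (img, _) in results.items():
            image_io.write_image(out / f"{label}.png", img)
        truth0 = results[conditions[0]][1]
        write_truth_csv(out / "truth.csv", truth0.minutiae)
    return results


def write_truth_csv(path, minutiae: list[Minutia]) -> None:
    """Ground-truth minutiae CSV: ``x,y,type,quality`` (0-based pixel coords)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y", "type", "quality"])
        for m in minutiae:
            w.writerow([f"{m.col:.1f}", f"{m.row:.1f}", m.kind, "" if m.quality is None else f"{m.quality:.2f}"])


def read_truth_csv(path) -> list[Minutia]:
    """Read a minutiae CSV written by :func:`write_truth_csv`."""
    out: list[Minutia] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            q = row.get("quality") or None
            out.append(
                Minutia(
                    row=float(row["y"]),
                    col=float(row["x"]),
                    kind=row["type"],
                    quality=float(q) if q else None,
                )
            )
    return out


__all__.append("write_truth_csv")
__all__.append("read_truth_csv")
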