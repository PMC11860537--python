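"""End-to-end orchestration of the fingerprint quality pipeline.

One image travels: channel selection → ROI crop → foreground mask →
brightness-error correction → mean/variance normalization → Sobel gradients →
block orientation (raw + smoothed) → block ridge frequency → Gabor
enhancement → binarize/thin → minutiae extraction + quality scoring →
(optional) ground-truth matching → quality counts.  An experiment maps a
subjects x conditions manifest through the pipeline and feeds the resulting
count table into the repeated-measures statistics layer.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import brightness, gabor, image_io, minutiae as mq, ridge_field, segment
from .stats_rm import CountTable, rm_anova, dunnett, tukey, comparisons_frame

__all__ = ["PipelineConfig", "ImageResult", "run_single", "run_pipeline", "run_experiment"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable stage parameter, with its standard default."""

    # segmentation / background blur
    blur_sigma: float = 50.0
    blur_window: int = 99
    # ROI
    roi_width: int = 1200
    roi_height: int = 800
    crop_roi: bool = False  # crop only when inputs are larger than the ROI
    # normalization targets
    target_mean: float = 100.0
    target_var: float = 100.0
    # orientation / frequency fields
    block_size: int = 40
    smooth_window: int = 5
    smooth_sigma: float = 1.0
    min_peak_distance: float = 4.0
    min_coherence: float = 0.1
    # Gabor
    sigma_ratio: float = 0.4
    psi: float = 0.0
    gamma: float = 1.0
    # minutiae / matching
    border_margin: int = 16
    match_radius: float = 10.0
    quality_thresholds: tuple[float, ...] = (0.7, 0.8, 0.9)
    # misc
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["quality_thresholds"] = list(self.quality_thresholds)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "quality_thresholds" in d:
            d["quality_thresholds"] = tuple(d["quality_thresholds"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


@dataclass(frozen=True)
class ImageResult:
    """All artifacts the pipeline produced for one image."""

    mask: np.ndarray = field(repr=False)
    normalized: np.ndarray = field(repr=False)
    orientation: ridge_field.OrientationField = field(repr=False)
    frequency: ridge_field.FrequencyField = field(repr=False)
    enhanced: np.ndarray = field(repr=False)
    minutiae: list = field(repr=False)
    truth: list | None = field(repr=False, default=None)
    counts: mq.QualityCount | None = None


def _prepare_gray(img: np.ndarray, light: str | None, config: PipelineConfig) -> np.ndarray:
    if img.ndim == 3:
        img = image_io.select_channel(img, light) if light else image_io.to_grayscale_average(img)
    H, W = img.shape
    if config.crop_roi and (W > config.roi_width or H > config.roi_height):
        img = image_io.extract_roi(img, "auto", (config.roi_width, config.roi_height))
    return img


def run_single(
    img: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    light: str | None = None,
    truth: list | None = None,
) -> ImageResult:
    """Run the full chain on one in-memory image."""
    gray = _prepare_gray(np.asarray(img, dtype=np.float64), light, config)
    mask = segment.make_mask(gray, sigma=config.blur_sigma, window=config.blur_window)
    deco = brightness.correct_brightness(
        gray, mask, sigma=config.blur_sigma, window=config.blur_window
    )
    norm = brightness.normalize(
        deco.corrected, mask, target_mean=config.target_mean, target_var=config.target_var
    )
    gx, gy = ridge_field.sobel_gradients(norm)
    fld = ridge_field.block_orientation(gx, gy, config.block_size)
    frac = ridge_field.block_mask_fraction(mask, config.block_size)
    fld = ridge_field.smooth_orientation(
        fld, config.smooth_window, config.smooth_sigma, weights=frac ** 2
    )
    freq = ridge_field.block_frequency(
        norm,
        fld,
        mask,
        min_peak_distance=config.min_peak_distance,
        min_coherence=config.min_coherence,
    )
    freq = ridge_field.regularize_frequency(freq, mask_fraction=frac)
    enhanced = gabor.enhance(
        norm, fld, freq, mask, sigma_ratio=config.sigma_ratio, psi=config.psi, gamma=config.gamma
    )
    skel = mq.binarize_and_thin(enhanced, mask, config.block_size)
    found = mq.extract_minutiae(skel, mask, border_margin=config.border_margin)
    found = [
        replace(m, quality=mq.score_quality(m, fld, enhanced)) for m in found
    ]
    labeled_truth = None
    counts = None
    if truth is not None:
        found, labeled_truth = mq.match_minutiae(found, truth, radius=config.match_radius)
        counts = mq.quality_counts(found, thresholds=config.quality_thresholds)
    else:
        warnings.warn("no ground truth supplied; TP/FP labels and counts unavailable")
    return ImageResult(
        mask=mask,
        normalized=norm,
        orientation=fld,
        frequency=freq,
        enhanced=enhanced,
        minutiae=found,
        truth=labeled_truth,
        counts=counts,
    )


def run_pipeline(
    config: PipelineConfig,
    image_paths: list,
    truth_paths: list | None = None,
    lights: list | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Process a batch of image files; returns one row of counts per image."""
    from .synthetic import read_truth_csv

    rows = []
    for idx, path in enumerate(image_paths):
        img = image_io.read_image(path)
        truth = None
        if truth_paths is not None and truth_paths[idx]:
            truth = read_truth_csv(truth_paths[idx])
        light = lights[idx] if lights else None
        res = run_single(img, config, light=light, truth=truth)
        c = res.counts
        rows.append(
            {
                "image": str(path),
                "n_minutiae": len(res.minutiae),
                "n_tp": c.n_tp if c else np.nan,
                "n_fp": c.n_fp if c else np.nan,
                "n_tp_09": c.n_tp_09 if c else np.nan,
                "survival_sum": c.survival_sum if c else np.nan,
            }
        )
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            stem = Path(path).stem
            image_io.write_image(out / f"{stem}_enhanced.png", res.enhanced)
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = config.config_hash
    return df


def run_experiment(
    config: PipelineConfig,
    manifest: pd.DataFrame,
    metric: str = "survival_sum",
    control: str | None = None,
    images: dict | None = None,
):
    """Run the pipeline over a subject x condition manifest and analyze it.

    ``manifest`` needs columns ``subject, condition`` plus either
    ``image, truth`` paths or, when ``images`` is given, keys into that
    in-memory ``{(subject, condition): (array, truth_minutiae)}`` mapping.
    ``metric`` selects the response analyzed (``survival_sum`` or
    ``n_tp_09``).  With a ``control`` condition the post hoc is Dunnett vs
    that control, otherwise Tukey all-pairs.

    Returns ``(counts_long_df, anova_report, comparisons_df)``.
    """
    from .synthetic import read_truth_csv

    required = {"subject", "condition"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    cells = manifest.groupby(["subject", "condition"]).size()
    subjects = manifest["subject"].unique()
    conditions = manifest["condition"].unique()
    missing = [
        f"{s}/{c}" for s in subjects for c in conditions if (s, c) not in cells.index
    ]
    if missing:
        raise ValueError(f"incomplete manifest; missing cells: {', '.join(missing)}")
    if len(subjects) < 2:
        raise ValueError("repeated-measures design needs at least 2 subjects")

    rows = []
    for _, rec in manifest.iterrows():
        if images is not None:
            img, truth = images[(rec["subject"], rec["condition"])]
        else:
            img = image_io.read_image(rec["image"])
            truth = read_truth_csv(rec["truth"]) if rec.get("truth") else None
        res = run_single(img, config, light=rec.get("light"), truth=truth)
        c = res.counts
        rows.append(
            {
                "subject": rec["subject"],
                "condition": rec["condition"],
                "n_tp_09": c.n_tp_09 if c else np.nan,
                "survival_sum": c.survival_sum if c else np.nan,
                "n_tp": c.n_tp if c else np.nan,
                "n_fp": c.n_fp if c else np.nan,
            }
        )
    long_df = pd.DataFrame(rows)
    table = CountTable.from_long(long_df, value=metric)
    report = rm_anova(table)
    comps = dunnett(table, control, seed=config.seed + 7) if control else tukey(table)
    comp_df = comparisons_frame(comps)
    comp_df.attrs["config_hash"] = config.config_hash
    return long_df, report, comp_df
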