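# Methods

This note documents the models, parameter choices and numerical decisions
behind `ridgekit`, and what the synthetic benchmark does and does not show
about real FTIR captures.

## Processing model

An FTIR capture is modeled as a bright, roughly elliptical contact footprint
on a dark background, carrying a locally sinusoidal ridge texture plus two
degradations: a smooth low-frequency brightness-error field (uneven contact
pressure, light/tissue interaction) and pixel noise. The pipeline removes
the degradations in that order — mask, background decomposition,
normalization — then estimates the two local parameters a matched filter
needs (ridge-normal angle and ridge period) and applies a block-adaptive
Gabor filter before minutiae extraction.

### Segmentation

The binarization threshold is computed on a blurred copy so that dark ridge
valleys inside the footprint cannot split the foreground class. The blur is
a normalized, truncated Gaussian, σ = 50 px with a 99 × 99 window (the
stated operating values for full 1200 × 800 captures; both are exposed as
parameters — on images much smaller than that, a proportionally smaller σ
segments more of the footprint rim). Otsu's criterion is maximized by an
exhaustive scan over the 255 split points of a 256-bin histogram built on
rounded intensities; ties resolve to the smallest optimal threshold so the
result is deterministic. Thresholding is followed by largest-component
selection and hole filling, since the physical contact region is a single
simply connected blob. All convolutions in the package reflect at the image
edge (the edge sample is included, `scipy`'s `reflect` mode).

### Brightness correction and normalization

The background estimate is a Gaussian blur of the masked image **divided by
the blur of the mask indicator**. A plain blur would average in the zeroed
background near the footprint rim and bias the background exactly where
pressure errors concentrate; the mask-normalized form is unbiased for
constant foregrounds all the way to the rim. The correction subtracts the
estimated background and adds back its foreground mean, so the decomposition
identities `masked = ridge + background` and `corrected = ridge +
mean(background)` hold to float precision, and the spatial statistics are
computed over foreground pixels only (including the zeroed background would
make them meaningless). Normalization maps the foreground affinely to mean
100 and population variance 100 — written piecewise around the mean, the
two branches are exactly the single affine map `m₀ + (I − m)·√(v₀/v)` — and
the background is set to the flat value 100 so the mask boundary feeds no
artificial edge into the gradient stage.

### Orientation field

Per 40 × 40 block, the ridge-normal angle is the doubled-angle average of
Sobel gradients, computed with the two-argument arctangent (the
single-argument form is undefined when the denominator vanishes and is
quadrant-ambiguous), folded into (−π/2, π/2]. Smoothing operates on the
continuous vector field (cos 2θ, sin 2θ) with a 5 × 5-block Gaussian of σ =
1 block: the doubled-angle embedding makes +89° and −89° near neighbors, so
no smoothing artifact appears at the wrap. The vectors are weighted by
block coherence — `√(Vₓ² + V_y²) / Σ(gₓ² + g_y²)` — times the squared
foreground fraction of the block before blurring. Without the weighting,
two contamination paths violate the estimator's own accuracy contract on
elliptical footprints: background blocks contribute arbitrary angles, and
rim blocks contribute the (strong, coherent) footprint-edge direction rather
than a ridge direction. Measured on noiseless synthetic fields, the
weighting reduces the interior-block mean absolute error from ≈ 2–3° to
≈ 0.6–1.8°.

### Ridge frequency

Each block is resampled (bilinear, on an implicitly oversized neighborhood)
in a frame rotated so the ridge normal is the row axis, rows are averaged
into a 1-D profile, and maxima are located where the forward difference
changes sign from positive to negative. Two numerical choices matter:

* **Sub-pixel refinement.** Integer maxima quantize the mean spacing; with
  a 12-px period only ~3 maxima fit a 40-px window and the quantization
  error approaches the ±0.5 px accuracy target. A 3-point parabolic fit
  around each maximum removes this error.
* **Noise gate.** Maxima closer than 4 px (half the minimum resolvable
  period) to the previously kept one are discarded as noise. The threshold
  is a package convention, exposed as `min_peak_distance`.

Blocks with fewer than two surviving maxima, coherence below 0.1, or less
than half their area in the mask are invalid. The per-block estimates are
then regularized: a 3 × 3 median over valid neighbors suppresses outliers,
and invalid foreground blocks inherit the median of their valid neighbors
(iterated); regions with no valid neighbor anywhere stay invalid and render
black in the enhanced output. Without the fill, every invalid block erases
the minutiae it contains, which measurably depresses true-positive recall
on noisy captures.

### Gabor enhancement

One even (cosine) Gabor kernel per block, built from the block's smoothed
angle and regularized period with ψ = 0, γ = 1, σ = 0.4 λ. The support is
`2⌈3σ⌉ + 1` (≈ 1% truncated envelope mass) and the kernel is mean-corrected
before use: the raw cosine kernel has a nonzero DC gain at small λ/σ, which
would re-introduce the brightness errors the earlier stages removed. Block
seams are left unblended (the block-wise character of the method is visible
by design). The valid output area is rescaled linearly to [0, 255].

### Minutiae and quality

The enhanced image is binarized at per-block medians (the enhanced signal
is zero-mean per block, so the median sits at the ridge/valley boundary),
thinned to a 1-px skeleton, and classified by crossing number. Two artifact
filters follow: minutiae within 16 px of the mask edge are suppressed
(ridges truncated by the footprint are not endings), and opposite-type pairs
closer than 4 px are removed as spur/bridge artifacts.

The per-minutia quality index is an explicit stand-in for an extractor's
proprietary indicator, preserving its observable contract — range
[0.01, 0.99], 0 reserved for background, monotone in local signal quality:

    q = clip(0.5·coherence(block) + 0.5·min(1, IQR(patch)/127.5), 0.01, 0.99)

with a 17 × 17 patch of the enhanced image. The contrast term saturates at
an interquartile range of half the 8-bit span: a cleanly enhanced ridge
patch then earns full credit, which matches the empirical behavior of
extractor-assigned indices (on usable real captures essentially all detected
minutiae score ≥ 0.7, so the 0.7/0.8/0.9 survival thresholds are
informative rather than vacuous).

Matching against ground truth is greedy one-to-one in order of increasing
distance, requiring type equality and a distance cap (default 10 px; tests
validate the greedy labels against a maximum-cardinality oracle). For
experiments on synthetic imagery with period-8 ridges the utility analyses
use a 4-px cap — half the ridge period — because a cap wider than the
period can "match" a detection sitting on the neighboring ridge, which at
high spurious-detection densities saturates the TP count by chance alone.

Quality counts follow the two summaries used for condition comparisons:
`n_tp_09`, the number of TPs with q ≥ 0.9, and the survival sum
`Σ_{t ∈ {0.7, 0.8, 0.9}} #{TP : q ≥ t}`, which weights better minutiae up
to three-fold.

## Statistics

The subjects × conditions count table is analyzed with the classical
repeated-measures one-way ANOVA (two-way additive decomposition, subjects as
blocks), assuming sphericity; a Greenhouse–Geisser toggle exists but is off
by default. Post hoc procedures:

* **Dunnett (vs control).** Per-contrast paired t statistics
  (SE = SD(control − test)/√n, df = n − 1); familywise adjustment from the
  max-|t| distribution over the k − 1 contrasts, which share the control
  column and are therefore equicorrelated at ρ = 0.5. The tail is computed
  by seeded Monte Carlo on the equicorrelated multivariate t (2·10⁵ draws
  by default, standard error of the adjusted p below ~1.2·10⁻³) and floored
  at the unadjusted p, making multiplicity monotonicity exact. With one
  contrast the procedure reduces to the paired t test exactly.
* **Tukey (all pairs).** Studentized-range tail with parameters
  (k, (k−1)(n−1)) on the pooled-MS_error scale; the per-pair SE reported in
  output tables is the paired-difference SE, which is what varies row to row
  in within-subject designs. The reported p matches R's `ptukey`.

Stars follow the GraphPad legend: ns p > 0.05, `*` ≤ 0.05, `**` ≤ 0.01,
`***` ≤ 0.001, `****` ≤ 0.0001, boundaries inclusive toward more stars.

Counts are treated as continuous responses; no generalized-linear
alternative is attempted.

## Synthetic benchmark: what it emulates, and what not

The generator produces ridge texture from an **analytic phase map**, not
filtered noise, so orientation and period ground truth are exact: constant
and "linear" (concentric arcs about a distant center) fields have unit
phase-gradient magnitude everywhere (exact period), and the "core" model
realizes a loop singularity (doubled-angle circulation 2π) via confocal
parabolas whose local period varies as √(r/r_ref). Minutiae are induced by
adding 2π phase dislocations at random interior positions; the recorded
dense orientation includes their analytic gradient terms. Ground-truth
minutiae are defined operationally: skeletonize the clean, noiseless binary
pattern and classify by crossing number — the same geometric definition the
detector applies, evaluated on the undegraded signal, so truth is invariant
under degradation by construction.

Degradations: a white-noise field blurred at `brightness_error_scale/4` and
peak-normalized to `brightness_error_amplitude`, plus i.i.d. Gaussian pixel
noise, clipped to [0, 255]. Condition presets map moisture (WC/UC/DC) and
illumination (R/G/B) labels to contrast/noise/brightness-error settings
encoding the qualitative physics — wet contact couples skin to plate best,
red light penetrates deepest and diffuses the ridge signal. The presets are
illustrative operating points, **not** a calibrated optical skin model; no
quantitative moisture→statistics mapping exists to calibrate against.

Consequences for interpretation: passing recovery tests shows the
estimators are correct for locally sinusoidal ridge patterns with smooth
fields and the stated degradations. Real captures add pores, scars, creases,
dry-skin ridge discontinuities, nonlinear sensor response and pressure
dependent ridge widening, none of which are emulated; absolute counts and
effect sizes on synthetic imagery do not transfer to clinical data, only
the machinery for measuring them.

Field-recovery evaluations (orientation MAE, period accuracy) use
dislocation-free patterns, because each dislocation genuinely perturbs the
local period and orientation near itself — there the nominal scalar truth is
simply not the true local value. Minutiae and enhancement evaluations keep
dislocations.

## Problem sizes and defaults

Synthetic evaluations run on 480 × 320 images (12 × 8 blocks at W = 40) with
period-8 ridges — large enough for ≥ 40 fully interior blocks and 10–25
minutiae per capture. Generator defaults: contrast 0.7, noise SD 8,
brightness-error amplitude 20 at scale 200 px, 10 dislocations, footprint
semi-axes at 42% of each image dimension. The enhancement-utility
comparison uses noise SD 25, contrast 0.5, 25 dislocations over 20 seeds.
Statistical calibration uses 5000 null replicates of 20 × 3 tables. All
randomness flows from explicit seeds through named `numpy` generator
substreams; outputs are bit-identical across runs.

## Known limitations

* Sphericity is assumed in the RM-ANOVA default; with k = 3 conditions and
  strong heterogeneity of difference variances the omnibus p can be
  anti-conservative (use the GG toggle).
* The quality index is a stand-in; it preserves range and monotonicity but
  not the numeric scale of any particular extractor, so absolute survival
  sums are not comparable across extractors.
* The per-block (rather than per-pixel) Gabor filter leaves visible seams
  and can flip the ending/bifurcation type of a minutia whose topology is
  marginal; type-strict matching counts such flips as FP + miss.
* σ = 50 / window 99 segmentation constants are tuned to full-scale
  (1200 × 800) captures; much smaller images segment with a conservative rim
  unless σ is scaled down.
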