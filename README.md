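# ridgekit

Image-quality pipeline for FTIR (frustrated total internal reflection)
fingerprint captures, with a synthetic-data generator, minutiae-based
quality scoring and a repeated-measures statistics layer.

## The problem

Optical FTIR fingerprint scanners image the fingertip through a glass plate:
where skin touches the plate, total internal reflection is frustrated and the
ridges appear bright on a dark background. Image quality depends strongly on
skin condition (moisture) and on the illumination wavelength, and quality
differences are best quantified the way NIST does — by counting correctly
extracted minutiae (ridge endings and bifurcations) weighted by a per-minutia
quality index. `ridgekit` implements the full processing chain needed for
such studies:

1. **Channel selection & ROI** — keep the sensor channel matching the R/G/B
   illumination; crop a 1200 × 800 region of interest.
2. **Foreground mask** — Gaussian blur (σ = 50, window 99) to suppress ridge
   frequency content, then Otsu thresholding
   `T* = argmax_T ω₁(T)ω₂(T)(μ₁(T) − μ₂(T))²`, largest component, hole fill.
3. **Brightness-error correction** — model the masked image as
   `I = r + b_real` with `b_real = b_ideal + e`; estimate `b_real` by
   mask-normalized Gaussian blur, then `I_corr = (I − b_real) + mean(b_real)`.
4. **Normalization** — affine map of the foreground to fixed mean/variance
   `m₀ = v₀ = 100`.
5. **Orientation field** — Sobel gradients, per-block (W = 40) doubled-angle
   averaging `θ = ½ atan2(Σ2gₓg_y, Σ(gₓ² − g_y²))`, coherence-weighted
   smoothing of `(cos 2θ, sin 2θ)`.
6. **Ridge frequency** — rotate each block so the ridge normal is axial,
   project to a 1-D profile, average the spacing of its maxima.
7. **Gabor enhancement** — per-block zero-mean kernel
   `exp(−(x′² + γ²y′²)/2σ²)·cos(2πx′/λ + ψ)` with ψ = 0, γ = 1, σ = 0.4 λ.
8. **Minutiae & quality** — binarize/thin, crossing-number classification
   (CN = 1 ending, CN = 3 bifurcation), quality index in [0.01, 0.99],
   TP/FP labels against ground truth, and the two summary statistics:
   `n_tp_09` (TPs with q ≥ 0.9) and the survival sum over thresholds
   {0.7, 0.8, 0.9}.
9. **Statistics** — repeated-measures one-way ANOVA (subjects as blocks),
   Dunnett comparisons vs a control condition or Tukey all-pairs, with
   GraphPad-style star notation.

Clinical FTIR data are not publicly deposited, so the package ships a
first-class synthetic generator (`ridgekit.synthetic`): elliptical bright
footprint, analytically phased ridge texture with exact orientation/period
ground truth, phase-dislocation minutiae, low-frequency brightness-error
fields, pixel noise, and moisture/illumination condition presets (WC/UC/DC ×
R/G/B). Every stage is tested against this ground truth.

## Worked example

Eight synthetic "participants", each captured under wet (WC), untreated (UC)
and dry (DC) conditions sharing the same finger geometry, analyzed with the
survival-sum quality count and Dunnett comparisons against UC:

```python
import pandas as pd
from ridgekit.pipeline import PipelineConfig, run_experiment
from ridgekit.synthetic import SyntheticSpec, emit_condition_set

images, rows = {}, []
for subj in range(8):
    spec = SyntheticSpec(width=480, height=320,
                         orientation_model=("linear", -0.6, 0.6), seed=subj)
    out = emit_condition_set(spec, ["UC", "DC", "WC"])
    for cond, (img, truth) in out.items():
        images[(f"s{subj}", cond)] = (img, truth.minutiae)
        rows.append({"subject": f"s{subj}", "condition": cond})

long_df, report, comp_df = run_experiment(
    PipelineConfig(), pd.DataFrame(rows),
    metric="survival_sum", control="UC", images=images)
print(f"F({report.df_condition},{report.df_error}) = {report.F:.2f}, "
      f"p = {report.p:.2e}")
print(comp_df.round(3).to_string(index=False))
```

Output:

```
F(2,14) = 152.75, p = 3.10e-10
group_1 group_2  mean_1  mean_2  mean_diff  se_diff  p_adjusted significance
     UC      DC  17.375   4.000     13.375    0.944       0.000         ****
     UC      WC  17.375  21.125     -3.750    1.048       0.016            *
```

The wet condition yields significantly more high-quality true minutiae than
the untreated control (mean 21.1 vs 17.4, adjusted p = 0.016) and the dry
condition far fewer (4.0, adjusted p < 10⁻⁴) — the direction the degradation
presets encode: wet contact couples the skin to the plate best, dry contact
worst.

A CLI mirrors the library (`ridgekit synth|crop|mask|preprocess|field|
enhance|minutiae|stats|run`), e.g.:

```sh
ridgekit synth --width 480 --height 320 --seed 3 --out captures/
ridgekit mask captures/image.png captures/mask.png
ridgekit preprocess captures/image.png captures/mask.png captures/norm.png
```

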