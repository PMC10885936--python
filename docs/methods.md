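# Methods

## Signal model and parameter maps

Each voxel of a diffusion-weighted station is modelled as a monoexponential
decay `S(b) = S0·exp(−b·ADC)`. The fit is ordinary least squares on
`ln S(b)` over the acquired b-values — closed form, deterministic, and for
two b-values identical to the exact interpolant
`ADC = ln(S(b₁)/S(b₂))/(b₂−b₁)`. Signals are floored at 10⁻³ a.u. before the
logarithm so background voxels stay defined; an all-zero voxel yields
ADC = 0 with S0 at the floor. Nonlinear least squares would weight high-b
points differently but needs iteration and initialisation; for the SNR
regime of whole-body DWI the log-linear fit is the standard choice.

Negative ADC estimates are genuine noise outcomes and are **retained** in
the ADC map — removing them would imprint artificial boundaries. They are
clamped to zero only inside cDWI synthesis (`S_bc = S0·exp(−b_c·ADC)`),
where a negative exponent would amplify noise voxels above S0. The clamp is
confined to that one operation.

## Network input

Two dimensionless channels per slice:

* `ADC / 3.5×10⁻³ mm²/s` — a fixed physical scale (upper end of tissue ADC),
  negatives preserved;
* `ln S0 / max(ln S0)` with S0 floored at 1 before the log. The max is taken
  **per study** (all stations pooled): a per-slice or per-station max would
  rescale each slice independently and destroy the inter-slice contrast the
  segmenter relies on. If every S0 ≤ 1 the channel degenerates to zeros and
  a warning is logged.

Slices are resampled in-plane to 256 × 256 at 1.6 mm (bilinear, centred
zero-pad/crop). The architecture is size-parametric; reduced configurations
run natively on 64 × 64 phantom slices with no resampling.

## U-Net and losses

Standard 2D U-Net: four encoder levels of two 3×3 conv + batch-norm + ReLU,
2×2 max-pooling and dropout (rate 0.2) between levels; bottleneck at 1/16
resolution; decoder with stride-2 kernel-3 transposed convolutions, skip
concatenation, dropout and two further convolutions per level; 1×1 conv +
sigmoid head. Default filters 32/64/128/256 with bottleneck 512; the test
and benchmark configuration uses 8/16/32/64 with bottleneck 128.

The engine is plain numpy (im2col-style einsum convolutions, hand-derived
backward passes, Adam). Every backward pass is verified against central
finite differences in the test suite; computation follows the dtype of the
input, so float32 batches train fast while float64 inputs keep the gradient
checks at ~1e-9 relative error.

Four losses over soft counts `TP = Σy·p`, `FP = Σ(1−y)·p`, `FN = Σy·(1−p)`:
log-cosh Dice, Combo (`DL − ω·mean(y ln p + (1−y) ln(1−p))`, ω = 0.8 —
written literally, so the bracketed sum is ≤ 0 and the cross-entropy enters
with positive weight), Tversky, and Focal Tversky (`TL^γ`). Defaults
α = 0.7, β = 0.3, γ = 1.1 weight false negatives harder and focus small
regions — the right trade-off for a thin canal against a dominant
background. Counts are soft during training (differentiable) and hard for
reported metrics.

A smoothing constant (default 1) is added to the numerator and denominator
of the Dice/Tversky ratios: empty-truth/empty-prediction slices then score 0
and keep a finite gradient. `smooth=0` evaluates the literal formulas
(0/0 ≡ 0), which is what the exact-arithmetic tests use.

Training: Adam, initial LR 10⁻³, batch 8 slices, up to 150 epochs (30 in the
scaled-down benchmark). The LR halves when the monitored loss fails to
improve by more than 10⁻⁴ (absolute) for 10 consecutive epochs, flooring at
10⁻⁵; validation loss is monitored when a validation set exists, else
training loss. All randomness (init, shuffling, dropout) is seeded;
two runs with the same seed produce identical histories.

## Inference and post-processing

Per-slice probabilities are assembled superior → inferior on the composed
whole-body grid. Where the target grid requests a position with no acquired
slice (a station gap), probabilities are linearly interpolated along the
patient axis between the nearest predicted slices; positions beyond the
acquired range clamp to the nearest slice. The binary mask is
`probability ≥ 0.5`. Slices acquired twice (station overlap) are taken from
the more superior station — the simplest deterministic rule.

## Canal characterisation

In-canal ADC is modelled with a 2-component Gaussian mixture
(scikit-learn EM: k-means init, 5 restarts, tol 10⁻⁶, ≤ 500 iterations),
fitted per study in units of 10⁻³ mm²/s to keep EM well conditioned. The
lower-mean component is labelled spinal cord, the higher CSF — consistent
with the physiology (free water diffuses ~2× faster than cord tissue).
Variance collapse triggers a refit with a variance floor of 10⁻⁴.
A minimum of 50 values is required. Voxels are assigned to the component
with the larger posterior; ties go to cord. Cord/CSF volumes are reported
both from the hard assignment and as mixture weight × canal volume.

With overlapping components (σ ≈ 0.6–0.8 around means 1.7/3.2) the mixture
is weakly identifiable below a few thousand values; at n = 10,000 the means
recover to ±0.05×10⁻³ mm²/s averaged over 20 seeds.

## Harmonisation and standardisation

The cDWI stations are composed on one slice grid; each boundary contributes
a scalar factor `s*` minimising `Σ_q (F_upper(q) − F_{s·lower}(q))²`, where
F are empirical cumulative frequency curves of the **nonzero** voxels from
3 slices on either side (background exclusion keeps padding from biasing
the factor), evaluated on a common 256-level grid spanning the pooled
range. The minimiser is a deterministic zooming grid search (200-point
log-spaced scan over [0.1, 10], two refinements, relative resolution
< 10⁻⁴); the ECDF objective is piecewise flat, so a grid beats a smooth
optimiser, and ties on a zero plateau resolve to the factor nearest 1.
Factors accumulate downward from the most superior (reference) station.

The harmonised volume is divided by the 90th percentile
(linear-interpolation definition) of in-canal signal. All operations are
multiplicative: within-station intensity ratios, and hence contrast-to-noise,
are exactly preserved, and the output is invariant to global intensity
scaling. An empty canal mask or non-positive reference is an error.

## Phantoms

The generator emulates the targeted acquisition: 4–5 stations (default 4)
of 40 axial slices (reducible), 64–256 matrix at 1.6 mm, thickness 5 mm,
b = 50/600/900 s/mm², per-station multiplicative gains, and a spinal canal
as a cylinder through all slices — cord core (ADC ~ N(1.7, 0.35) ×10⁻³,
weight 0.6) inside a CSF ring (N(3.2, 0.60), weight 0.4), radii 6.2/8.0 mm
so the area ratio matches the weights. A body ellipse provides background
tissue (ADC 1.0×10⁻³); optional lesions are low-ADC (0.7×10⁻³), high-S0
spheres outside the canal. Noise is Rician (magnitude of a complex Gaussian
perturbation), matching magnitude MRI. The canal centre is randomised per
phantom within the central third of the field of view so a segmenter must
use contrast, not position.

Deliberate simplifications: per-voxel ADC draws are i.i.d. (no spatial
texture), there is no anatomy beyond the body ellipse, and no EPI
distortion, ghosting or bias field. Passing tests therefore demonstrate the
correctness of the pipeline's mechanics and its recovery of known gains and
mixture parameters — not robustness to real anatomical variability, which
needs patient data.

## Scaled-down segmentation benchmark

15 phantoms (two stations × 12 slices, 64 × 64, gains drawn once from
U(0.8, 1.2), Rician σ = 10 a.u. against S0 of 200–900, i.e. SNR ≈ 20–80),
split **by phantom** 10/2/3 (70/15/15) to avoid slice leakage; the reduced
U-Net trains for 30 epochs with Focal Tversky defaults (~240 training
slices, a few minutes on one CPU). Metrics are patient-wise Dice, precision
and recall of the predicted canal mask over each whole phantom volume. The
synthetic task is easier than real anatomy, so the full-scale reported
levels (validation Dice 0.871; all test metrics ≥ 0.87) act as lower
bounds the benchmark must clear.

## Numerical conventions

* Arrays are (slice, row, col), 0-based, slice index increasing superior →
  inferior; masks share the grid of their source volume.
* Dice/precision/recall of two empty masks are defined as 1 (logged).
* Both masks empty ⇒ loss 0; probabilities are clipped to
  [10⁻⁷, 1−10⁻⁷] inside cross-entropy.
* NIfTI is the canonical interchange format (float32 maps, uint8 masks);
  DICOM is read-only ingestion keyed on the (0018,9087) b-value attribute.
* Checkpoints are `.npz` weight archives with a JSON sidecar recording the
  architecture, loss, training configuration and seed.

## Known limitations

* The numpy engine is CPU-only; full-scale training (256 × 256, filters up
  to 512) is possible but slow — the package targets method validation and
  moderate-size studies rather than large-cohort training.
* The GMM assumes exactly two tissue classes inside the canal; lesions or
  partial-volume voxels inside the canal would perturb the split.
* Harmonisation assumes a purely multiplicative gain difference between
  stations; spatially varying bias fields are out of scope.
* DICOM ingestion reads single-station series only and does not handle
  multi-frame enhanced DICOM.
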