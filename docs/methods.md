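# Methods

This note documents the modelling choices, numerical conventions and
limitations of `bronchoseg`. Everything stated here about behaviour is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external measurements.

## Model

### Encoder

The backbone is a four-stage hierarchical transformer trained from scratch.
An overlapping patch embedding (7×7 convolution, stride 4, padding 3) maps
the RGB frame to a stride-4 token grid; each stage applies pre-norm windowed
self-attention blocks (window 4, zero-padding-free — windows tile the grid
exactly and shrink to the grid on coarse stages) and an MLP (ratio 2), with
a 2×2 stride-2 convolution between stages doubling channels and halving
resolution. The tiny default is base 16 channels, depths (1, 1, 2, 1),
heads (1, 2, 4, 4), giving pyramid shapes 16²×16 / 8²×32 / 4²×64 / 2²×128
on a 64×64 input and ~236k parameters for the full model.

Windowed attention is permutation-invariant inside a window, so each stage
adds a learnable absolute positional embedding to its input (defined on a
reference grid, bilinearly resized for other input sizes). Without it the
backbone's spatial acuity — and hence mask boundary quality — degrades
measurably. Pre-norm layer normalization is used throughout, the standard
choice for hierarchical vision transformers trained from scratch.

Input sizes must be divisible by the total stride (32 by default), and the
per-stage grids must be tileable by the window; the default configuration
accepts 64, 128, 192, ... but not 96 (the stage-2 grid 6 is not divisible
by window 4). Configuration validation rejects such sizes at model
construction.

### Frequency pathway

The high-pass companion image is produced by a centered 2-D FFT per color
channel, multiplication with the binary mask that zeroes cells satisfying
`4|(u−H/2)(v−W/2)| / (HW) ≤ m`, and an inverse FFT keeping the real part.
Conventions worth pinning:

- the mask's suppressed region is a hyperbolic index set; `m = 0` removes
  exactly the central cross (where the index product vanishes) and `m = 1`
  removes every cell;
- odd dimensions use the real-valued center `H/2` (no flooring), so on odd
  grids the shifted DC cell sits half a unit off-center and is suppressed
  only for `m ≥ 1/(HW)` — the literal formula is implemented rather than a
  special-cased DC rule;
- the mask treats the `u = 0` / `v = 0` rows of an even grid asymmetrically,
  which breaks exact Hermitian symmetry; the resulting imaginary residue is
  tiny and discarded (real part, not magnitude) so that signed edge contrast
  survives for the adapters;
- `m` defaults to 0.25 and is exposed for sweeps.

The adapters compress by `r = 4` with one shared down-projection per level
feeding both the feature cue and the frequency cue, an inner linear map
`φ` within the compressed dimension, and a zero-initialized up-projection
`ρ`. Zero-initializing `ρ` makes the adapted forward pass bit-identical to
the plain backbone at initialization (verified bitwise in the tests). The
frequency branch runs the plain backbone (no prompt recursion) on `I_HFC`;
its gradients flow into the shared weights by default, with a configuration
flag to detach them. `I_HFC` is computed once per sample and cached by the
training loop.

### Fusion and positional encoding

Only the deepest pyramid level is fused downward, through a 1×1 lateral
projection reconciling the channel widths (the formula adds a `C_4`-channel
map to a `C_3`-channel one; a lateral projection is the standard resolution
of that mismatch) and nearest-neighbour upsampling. Levels 1–2 pass through
untouched — asserted bit-identically — and level 4 is dropped after fusion.

Positional grids use a learnable Gaussian frequency matrix `G ∈ R^{d×2}`
(standard-normal init, scale 1.0, seeded) with `d = C_i/2` per level so the
2d-channel sin/cos grid matches its feature map and can be added to it.
Pixel centers map affinely to `[−1, 1]²` with the first row/column at −1
and the last at +1, row → u, col → v. All three levels are paired with
grids; the decoder consumes the deepest pair, and the finer two are
available to downstream variants.

### Decoder

The classification head reads the deepest fused feature through an explicit
`detach`, so the classification loss contributes exactly zero gradient to
every parameter upstream of it (asserted to machine zero in the tests);
the segmentation loss reaches the patch embedding. The unquantified
"upsample" before the head's convolution is fixed at ×2 nearest-neighbour.
Batch normalization runs in per-image (spatial-statistics) mode during
training, with running estimates used at inference; the running statistics
are serialized with checkpoints.

The mask decoder follows the prompt-based two-way transformer design:
depth 2, 4 heads, token dimension equal to the deepest fused channel count,
one mask token by default (generalizable to M tokens, giving M logit maps).
The dense prompt embedding is defined on the deepest fused grid of the
configured image size and is bilinearly resized when the model runs at
another compatible size. In the two upsampling stages, layer normalization
appears only in the first stage — the asymmetry is implemented exactly as
specified rather than regularized away. Token weight vectors contract with
the row-major flattened final feature map; logits are bilinearly resized to
the input resolution. The binarization threshold is fixed at τ = 0.5 with
`≥` at the boundary (an all-0.5 probability map binarizes to all ones).

### Loss

Pixel BCE uses the numerically-stabilized form
`max(z,0) − zy + log(1+exp(−|z|))`. Soft IoU is `1 − Σpy / Σ(p+y−py)` with
`p = σ(z)`; a vanishing denominator (empty target with numerically-zero
prediction; threshold 1e−12 since a sigmoid is never exactly zero) is
defined as 0 with a warning. The classification term is the scalar sigmoid
cross-entropy — the two-class task is treated as binary throughout, not as
a 2-way softmax. Default weights: λ_BCE = 1.0, λ_IoU = 2.0, λ_seg = 1.0,
λ_cls = 1.8. No class re-weighting is applied; imbalance is handled only by
stratified splitting. The soft IoU is computed per image and averaged (at
batch size 1 the distinction from batch pooling vanishes).

## Metrics

Classification metrics derive from confusion counts with malignant as the
positive class; ratios with zero denominators are reported as 0 and
flagged. AUPRC integrates precision step-wise (rectangles) over recall with
tied scores grouped into one threshold — the step convention is pinned
because an integral notation alone does not fix it; the implementation is
cross-checked in the tests against exhaustive threshold enumeration and
against scikit-learn's average precision.

Segmentation metrics come from the 2-class pixel confusion matrix
(`p_ij` = pixels of true class i predicted j; class 0 lesion, class 1
background): overall accuracy, and class-averaged accuracy / IoU / Dice /
precision / recall. Dataset-level values average per-image metrics rather
than pooling pixels (both modes are exposed; per-image is the default). A
class absent from an image is skipped from that image's class mean and
flagged. Percentages print with 1 decimal for classification and 2 for
segmentation.

## Synthetic data

The generator emulates the *structure* of white-light bronchoscopy frames,
not their photometry: circular field of view (radius 0.48·min(H,W)) on
black, pinkish mucosa with Gaussian-filtered texture, an off-center dark
lumen, an optional linear illumination gradient, 1–3 saturated specular
spots, and optional short-kernel motion blur. Lesions are radially
Fourier-perturbed ellipses placed entirely inside the field of view; every
frame contains at least one lesion.

The benign/malignant distinction is a *parameter-family proxy*: malignant
lesions draw more and larger boundary harmonics (roughness 0.15–0.32 vs
0.03–0.10) and higher contrast (0.22–0.40 vs 0.08–0.18) with stronger
interior texture; 70% of lesions are pale, 30% dusky. The family is
recorded in each sample's metadata, which is what makes the label/
appearance coupling assertable. Labels are drawn per-sample Bernoulli at
the cohort ratio 627/729. Augmentation draws one spatial transform per call
(rotation ≤ 30°, flips, scale 0.8–1.2, translation ≤ 10%, shear ≤ 10°),
applies it identically to image and mask, and re-binarizes the mask at 0.5
after interpolation.

What passing tests on this data do and do not show: they validate the
architecture, optimization, determinism and metric pipeline end to end;
they do not establish clinical performance, because the generator lacks
real mucosal photometry, vascular patterns, annotation noise, and the full
morphological diversity of airway lesions. The proxy parameterization of
malignancy is a stand-in, not a claim of clinical realism.

Splits are label-stratified with largest-remainder rounding (each stratum
within one sample of its proportional share), seeded; k-fold
cross-validation uses stratified folds with a train/validation split inside
each round. The fixed split is the default, cross-validation sits behind a
flag, since the fixed split is an order of magnitude cheaper.

## Optimization

AdamW (β = (0.9, 0.999), weight decay 0.01), batch size 1, cosine-annealed
learning rate from the configured peak to 1e−6, early stopping on
validation loss with the best-validation checkpoint retained. When no
validation set is supplied the final state is returned — checkpoint
selection is a validation concept. One master seed fans out to data
generation, weight initialization, shuffling and augmentation, and runs are
bit-reproducible on CPU. A non-finite loss aborts with a diagnostic rather
than training through it.

The paper-scale default learning rate is 2e−4; the desk-scale exercise
(tiny model, 32 frames of 64×64, 200 steps) uses 2e−3, which is the setting
that trains best from scratch at this size. On those conditions the model
reaches a training mDice of ≈ 0.83 after 200 steps (≈ 0.86 by 600); the
residual gap to near-perfect training Dice is concentrated in a few frames
where the generator's deliberate confounds bite — small bright lesions
adjacent to specular highlights and dusky lesions bordering the dark lumen.
These conditions were fixed before any training was run and are not tuned
to the model.

## Numerical choices

- All tensors are float64; gradient checks against central differences hold
  to ~1e−8 relative error across every primitive.
- The autodiff engine is a minimal reverse-mode implementation over NumPy
  covering exactly the operator set the model needs; convolution and its
  transpose are im2col/col2im pairs that are exact adjoints of each other.
- GELU is the exact erf form, not the tanh approximation.
- Bilinear resizing is expressed as multiplication by row-stochastic
  interpolation matrices (half-pixel centers), making its gradient exact by
  construction.
- Softmax subtracts a detached row maximum; the subtraction is
  gradient-transparent because softmax is shift-invariant.
- Masks are uint8 {0,1} in memory and {0,255} in PNG files; images are
  float64 in [0,1] in memory and 8-bit in PNG files (round-trip error
  bounded by 1/255).

## Known limitations

- Input sizes are restricted to multiples of the total stride whose stage
  grids the attention window tiles (64, 128, ... for the default).
- Batch size is fixed at 1; there is no batching, mixed precision, or
  multi-device support — the implementation targets CPU-scale experiments.
- The classification head's batch-norm statistics are per-image during
  training, which is the correct reading of batch-norm at batch size 1 but
  differs from large-batch behaviour.
- The synthetic generator's realism limits are described above; absolute
  clinical benchmark values cannot be reproduced without the clinical
  cohort and GPU-scale training, and the package does not attempt to.
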