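# Methods

## The measurement and its model

The sagittal vertical axis (SVA) is computed from two landmarks on a
standing lateral radiograph: the C7 vertebral-body center and the
posterior-superior corner of S1. With landmarks in the original image frame
and a per-image physical calibration (mm per pixel, possibly different per
axis), the signed SVA is

```
SVA = (x_C7 − x_S1) · mm_per_pixel_x · facing_sign
```

`facing_sign` is +1 when the patient faces toward increasing x (anterior to
the right of the image), −1 otherwise, so positive SVA always means the C7
plumb line falls anterior to the sacral corner.

Landmarks are detected by heatmap regression: a convolutional network maps
the preprocessed radiograph to one regression-target image per landmark,
and the landmark estimate is the center of a function fitted to the
predicted map.

### Target families and the half-maximum coupling

Two target families share the width parameter σ (pixels):

* Gaussian `G = c·exp(−(Δx² + Δy²)/2σ²)`
* Exponential `E = c·exp(−α(|Δx| + |Δy|))`

α is never an independent parameter: it is defined by requiring both
families to reach half maximum at the same axis distance `σ·√(2 ln 2)`,
giving `α = √(ln 2 / 2)/σ`. With matched half-maximum contours, the
exponential has a sharper peak (less localization ambiguity) and heavier
tails along the axes (non-zero regression targets over a wider area, hence
more learning signal when σ is small). The amplitude defaults to `c = 1000`
("a large constant at the order of 10³"); all downstream localization is
amplitude-invariant.

Pixel convention: 0-based grids, the pixel in column i / row j is sampled
at integer coordinates (i, j), x is the column. Targets are rendered one
landmark per channel (order: C7, then the sacral corner), so localization
never has to separate or identify peaks.

### Network

The default model is a residual U-Net with 31 convolutions (24 3×3, 7 1×1):
a head block, four stride-2 residual downsamplings (768×448 → 48×28 at the
C5 bottleneck, 512 channels), four bilinear ×2 upsamplings each followed by
a channel-reducing residual block on the concatenation with the encoder
skip, and a three-conv tail ending in a linear layer with one channel per
landmark. Group normalization (32 groups by default) replaces batch
normalization because the training batch is 4. A plain 12-convolution UNet
(two max-pool halvings, concatenation skips, same conv/GN/ReLU styling)
serves as the complexity baseline; only its total layer count is
architecturally pinned, the layout is this package's choice.

Decisions where the architecture description was open:

* encoder/decoder skips merge by **channel concatenation**; block output
  widths follow the architecture table regardless of merged input width;
* in Res-Down, the **first 3×3 conv and the 1×1 projection use stride 2**
  (the halving in the shape table fixes this); everything else is stride 1;
* block internals are conv → group norm → ReLU, with the residual addition
  before the final ReLU; the skip path is not re-normalized;
* upsampling is bilinear with half-pixel centers, non-learnable;
* all convolutions are zero-padded ("same");
* weights are He-uniform (fan-in); the final linear head is additionally
  scaled by 0.01 (see *Numerical choices*).

### Preprocessing and augmentation

Every image is resized (anisotropically if needed) to a fixed 768×340 inner
region and zero-padded symmetrically to 768×448 (54 px per side); the wide
padding guarantees ±30° training rotations cannot clip the spine. The
affine coordinate map (half-pixel-center convention, matching the image
resampling) is recorded per image and inverted exactly when predictions are
taken back to the original resolution; all millimetre statistics are
computed there. Inputs already at the canvas size pass through unchanged
(identity transform) — the path synthetic phantoms use. Intensities are
normalized to [0, 1] by bit depth.

Augmentation draws scale ∈ [0.9, 1.1], rotation ∈ [−30°, 30°] and Gaussian
blur ∈ [0, 0.5] (the blur "strength" is the kernel SD in pixels) uniformly,
applies scale→rotate as a single bilinear affine pass about the canvas
center, and co-transforms the landmarks. A draw that would push a landmark
off-canvas is redrawn (up to 10 substream attempts) and then falls back to
identity, keeping the training count stable.

### Localization

Each predicted channel is fitted, over a square window of half-width
`max(7, ceil(4σ))` centered on its argmax, with the training-target family;
free parameters are center, amplitude and width. The Gaussian fit uses
Levenberg–Marquardt least squares; the exponential's L1 offset is
non-differentiable at the peak, so that family is fitted with a
derivative-free Nelder–Mead simplex on the squared error. Initial values:
argmax location, peak value, training σ. A failed or out-of-window fit
falls back to the integer argmax (ties resolve to the smallest row-major
index). Localization runs on raw predicted maps; the clip-and-normalize
probability view is for interpretation only. Leaving the fitted width free
(rather than frozen at the training σ) is a robustness choice; on noiseless
targets both coincide.

### Training protocol

MSE over all pixels and channels; SGD with Nesterov momentum 0.9; L2
strength 1e-5 applied to convolution kernels only (group-norm affines and
biases exempt); lr 0.01 halved on epoch 100 (1-based; the new rate applies
during epoch 100); 120 epochs; effective batch 4 as 2-per-replica × 2,
reproduced on one device by gradient accumulation (verified equivalent in
the tests); model selection by validation MSE restricted to epochs > 80,
ties to the earliest. Cross-validation uses a seeded uniform random
partition into k folds whose sizes differ by at most one (990/10 → ten
folds of 99).

## Synthetic phantoms

The generator emulates the *structure* of clinical whole-spine laterals so
every module is testable without patient data: a smooth spine axis (sine
curvature plus a linear lean; cranial/caudal framing margins drawn per
image), 18 rounded vertebral bodies shrinking toward the neck, a sacral
wedge whose posterior-superior vertex is the second landmark, background
gradient plus white noise, and optional bright shoulder-ellipse occluders
and implant-like rods. The C7-analogue landmark is the centroid of the
topmost body (exact by construction); annotation jitter is available (off
by default) for inter-rater pipeline tests. Facing is randomized by
mirroring; the signed SVA analogue spans both signs across a dataset.
mm-per-pixel factors are drawn from [0.8, 1.2] per axis.

Phantom i of a dataset is generated from `default_rng([seed, i])`, so
prefixes of larger datasets reproduce smaller ones exactly.

What the phantoms do **not** model: X-ray physics (beam divergence,
scatter), soft tissue, ribs/skull context, pathology diversity, and
annotation ambiguity. Passing desk-scale tests therefore demonstrates that
the pipeline's machinery is correct and that the target-family effect has
the expected direction — not clinical-grade accuracy.

## Numerical choices

* **Engine.** Layers run on an NCHW NumPy/numba engine (direct JIT loops
  for large feature maps, phase-decomposed loops for stride 2, im2col+GEMM
  below 1500 output pixels, BLAS for 1×1). Every layer's backward pass is
  verified against float64 central differences in the test suite.
* **Small-scale head init.** The regression targets are tiny relative to
  unit-variance features; a full-scale random head makes the initial output
  error so large that the fastest descent direction is to silence the
  output path entirely (a dead attractor via the normalization affine, from
  which gradients never recover). Scaling the final linear conv's init by
  0.01 starts the output near zero while keeping gradients alive.
* **Float64 master weights.** The optimizer keeps float64 master copies;
  per-step updates on this loss are routinely below the float32 ulp of the
  weights and would otherwise be rounded away. Compute stays float32.
* **Reduced models.** The penultimate tail width is `max(f/2, 2)` so that
  heavily reduced models never squeeze both landmark maps through a single
  channel; at the default width this is exactly the full-width value of 32.
* **GN variance** is computed as `E[x²] − E[x]²` on contiguous group slabs
  (fast on one CPU), clipped at zero, with ε = 1e-5.

## The desk-scale target-family experiment

The full protocol (990 radiographs, 768×448, 120 epochs, 10-fold CV) needs
~50 GPU-hours per sweep and private data. The package instead ships a
desk-scale comparison designed to reproduce the *direction* of the
narrow-width result — exponential targets are easier to learn than Gaussian
targets at σ = 1.57 — on one CPU:

* 300 training phantoms and 60 held-out phantoms at 192×112;
* reduced-width ResUNet (base 4 filters, 2 normalization groups);
* 15 epochs, no augmentation (isolates the target-family effect);
* 5-px detection of the C7 analogue, three seeds.

Because the full-scale optimizer pairing (amplitude ~10³, lr 0.01, batch 4)
needs tens of thousands of SGD steps to span the head-amplitude gap — the
original schedule takes ~26,700 steps — the desk run is recalibrated,
**identically for both families**: unit target amplitude, lr 0.1, batch 1
(4,500 steps at the same total compute), final-epoch weights. With this
recipe the exponential-target model reaches meaningful detection while the
Gaussian-target model lags, echoing the full-scale gap qualitatively; the
acceptance test asserts only the direction (exponential ≥ Gaussian in at
least 2 of 3 seeds), never its magnitude.

## Known limitations

* The engine is CPU-only and single-threaded; full-resolution training is
  out of reach (and out of scope).
* The exponential fit relies on a simplex search; on maps with very flat
  plateaus it can fall back to argmax (reported in the result's `method`).
* ICC confidence intervals use the standard F/Satterthwaite approximation;
  for degenerate variance structures the CI is collapsed and flagged.
* The phantom generator's realism limits are listed above; in particular
  occluders make C7 genuinely ambiguous in a fraction of images, which is
  intentional (the clinical failure mode it mimics) but caps attainable
  desk-scale detection rates.
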