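# Methods

## The estimation problem

Each tobacco leaf is imaged in six spectral bands; the targets are two mass
fractions of dried tissue, total nitrogen and nicotine (both in %, plausible
range 0.5–5). Nitrogen drives chlorophyll concentration and leaf structure,
so it moves broad-band reflectance — most strongly in the green (chlorophyll
reflectance) and NIR (internal structure / water) bands. Nicotine has no
comparable broad-band signature; its correlates are textural (venation and
surface microstructure). The pipeline therefore fuses per-band reflectance
means with a large texture bank and regresses each trait separately.

## Synthetic scene model

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is validated.

**Geometry.** A leaf is an ellipse (semi-axes `a`, `b` in fractions of the
canvas height) whose boundary radius is modulated by a 5-lobe cosine
(amplitude 0.06), rotated and placed on the canvas. Plant scenes place 5–7
leaves bottom-to-top along a stem, alternating sides, with droop angles drawn
per leaf. A placement loop pushes each new leaf outward until its pairwise
overlap (intersection / smaller area) is within the configured budget;
`overlap_fraction = 0` yields exactly disjoint masks, and an impossible
layout raises. Leaves are rendered bottom first, so upper leaves occlude
lower ones and every foreground pixel belongs to exactly one visible
instance mask (front-leaf-wins).

**Radiometry.** Noise-free leaf reflectance in band *k* is

    rho_k(x) = clip( (b0_k + b1_k * N) * (1 + tex(x)) * g, 0, 1 )

with nitrogen `N` in %, band intercepts/slopes

| band | b0 | b1 |
|------|------|-------|
| blue | 0.10 | 0.008 |
| green| 0.25 | 0.040 |
| red | 0.15 | 0.010 |
| red edge | 0.35 | 0.025 |
| NIR | 0.45 | 0.050 |
| pan | 0.20 | 0.020 |

(largest slopes in NIR and green), a per-leaf illumination gain
`g ~ LogNormal(0, 0.02)`, and a vein texture field

    tex = A(nicotine) * cos(2*pi * f(N) * (u/2 + |v|/4 + 1/2) + phase)

in leaf-local coordinates `(u, v)`, with amplitude `A = 0.04 * nicotine` and
frequency `f = 6 + 2 * N` cycles per leaf. Nicotine therefore appears *only*
in texture contrast, never in band means; nitrogen appears in both the means
and the vein frequency. Band images add i.i.d. Gaussian noise (default
σ = 0.01 reflectance units), are scaled by a per-band DN gain (default
10 000), and the pan band is rendered at 2× resolution from the same
fractional geometry. Plant scenes sit on a low-frequency soil-clutter field;
laboratory captures use a dark (0.02) background. A reflectance panel
(known reflectance 0.5) occupies a corner rectangle and is never occluded.

**Chemistry.** Within a plant, expected nitrogen interpolates linearly from a
bottom value to a top value (drawn from the lower/upper 30 % of the 1.5–4.5 %
range) and nicotine does the reverse over 1.5–3.5 %; realized per-leaf values
add N(0, 0.05²). Laboratory datasets draw chemistry uniformly over the
ranges. All randomness derives from `SceneSpec.seed`; identical specs produce
bit-identical files.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: photorealistic venation, lens parallax and band
misregistration, specular highlights and shadows, curved/drooping leaf
geometry distorting texture, and chemistry–geometry confounds beyond the
vertical gradient. Recovery results on this data demonstrate that the
pipeline extracts the signal it is pointed at, not field-level accuracy.

## Calibration

One-point empirical line per band: gain = known panel reflectance / mean
panel DN, applied to all pixels and clipped to [0, 1]. A one-point (gain
only) model matches a single-panel setup; panel reflectance and region are
configurable. Calibrating an already-calibrated capture raises rather than
double-scaling. Coordinates are row-major, 0-based, origin top-left;
rectangles half-open.

## Segmentation blocks

These are the custom computations of the leaf segmenter, implemented
standalone in NumPy; the surrounding detector (backbone/neck/head, assigners,
losses) is treated as an external architecture, and ground-truth masks are
the default segmentation source for the chemistry pipeline (detector training
is GPU-scale and data-bound).

**Aggregated attention.** For each query pixel, keys/values are the
`window_size²` local neighborhood (zero-padded positions are *excluded* by a
masked softmax, keeping weights normalized) plus `pool_size²` globally pooled
keys shared by all queries; softmax runs over the union, channels split
across heads. Q/K/V/O are pointwise projections. C2f_AA applies this
attention residually on top of a standard C2f (pointwise expansion, split,
residual 3×3 bottlenecks, concat, pointwise fuse), so disabling attention
recovers plain C2f exactly — the ablation oracle used in tests.

**OREPA.** Six parallel linear branches — 3×3 conv; 1×1→3×3 serial; 1×1→1×1
serial; fixed 3×3 mean filter + learned channel mixing; fixed 3×3 DCT cosine
basis (frequencies (0,1), (1,0), (1,1)) + learned mixing; depthwise 3×3 +
pointwise — each followed by a per-output-channel linear scaling vector, plus
one shared bias. Because every branch is linear with receptive field ≤ 3×3,
the block folds exactly into one 3×3 kernel: serial branches by kernel
composition, pointwise kernels by center embedding, fixed filters by
multiplication into the mixing weights. The internal branch hyperparameters
(serial expansion width, the cosine basis, the mean-filter construction) are
declared defaults; the compression-equivalence property (≤ 1e-4 over 100
random blocks, in practice ~1e-14) pins correctness regardless of those
choices. Analytic parameter gradients run through the folded kernel
(`orepa_param_grad`), which a finite-difference test confirms branch by
branch; a small gradient-descent harness (`fit_orepa`) provides the
training smoke test. OREPAGELAN wires OREPA units into a GELAN split /
partial-aggregation topology (SiLU between units); `compress()` swaps every
unit to its folded form — output preserved, parameter count strictly smaller
— and warns on a second call.

Numeric tolerance for all equivalence checks is 1e-4: float32-style
accumulation-order differences between the two forms, with large headroom.

## Segmentation metrics

Single category. Matching is greedy in descending score; each ground truth is
claimed at most once; a prediction is TP iff its best free ground truth has
IoU ≥ threshold. AP integrates the all-point interpolated precision-recall
curve (precision envelope × recall increments); mAP50-95 averages the ten
thresholds 0.50…0.95. mIoU is defined over ground-truth leaves: the IoU of
each leaf's greedily matched prediction, 0 if unmatched, background excluded.
IoU of two empty masks is an error, not 0. Metrics are validated against a
plain-Python set-arithmetic oracle on ≤ 10-instance cases.

## Feature bank

Texture is computed on the tight bounding-box crop with background zeroed —
the zeroed background is part of the signal exactly as a segmentation-based
pipeline sees it — which also makes features invariant to padding the scene
with more background. Crops smaller than the largest Gabor kernel are
zero-padded to its support (33 px at defaults) rather than rejected; the raw
`gabor_features` primitive still errors on undersized images.

Per band (79 features):

* **GLCM (5)** — 32 gray levels by min-max quantization, distance 1, angles
  {0°, 45°, 90°, 135°} with per-angle statistics averaged; symmetric,
  normalized matrix; energy := √ASM; constant images take the degenerate
  convention contrast 0, dissimilarity 0, homogeneity 1, energy 1,
  correlation 1.
* **LBP (10)** — rotation-invariant-uniform-style histogram at P = 8, R = 1:
  the uniform patterns fall into P + 2 = 10 classes, the unique standard
  construction yielding exactly ten statistics for eight neighbors. Images
  are 8-bit quantized first to avoid float ties.
* **Fourier (4)** — mean/std of the unshifted DFT magnitude and phase
  (phase in (−π, π]); validated by Parseval's identity.
* **Gabor (48)** — wavelengths {4, 8, 16, 32} px × orientations
  {0°, 45°, 90°, 135°}; σ = wavelength/4, kernels truncated at 2σ; per filter
  the mean, std and energy (Σ magnitude²) of the complex response.
* **Wavelet (12)** — single-level Haar decomposition; per sub-band (LL, LH,
  HL, HH) the energy, variance, and Shannon entropy (base 2, 0·log 0 := 0) of
  the normalized squared coefficients. Haar's orthonormality gives the
  energy-conservation test.

Plus the six masked spectral means: 6 + 6 × 79 = 480 features with stable
canonical names (`band_mean.green`, `nir.wavelet.hh.energy`, …). The pan band
contributes its own 79 features at native resolution; no pan-sharpening.

## Screening, augmentation, split

Pearson screening uses |r| with a strict `>` threshold (ties at the boundary
are excluded by strictness; zero-variance features score 0). The variance
screen uses raw-feature sample variance (ddof 1); its threshold is exposed as
configuration since retained counts are data-dependent. LASSO/Elastic-Net run
on internally z-scored features via coordinate descent; the Elastic-Net
penalty is parameterized directly as `l1·||w||₁ + l2·||w||₂²` and mapped to
the solver's (α, l1_ratio); `l1 = 0` falls back to ridge (no selection),
strength 0 to least squares. Coefficients below 1e-10 in magnitude count as
zero — coordinate descent leaves ~1e-16 dust on duplicated columns which is
not a genuine selection. Default strengths come from internal
cross-validation; fixed values reproduce a given selection size.

Augmentation (training partition only, enforced): each copy is
`(x + ε)·s + o` with elementwise ε ~ N(0, 0.01), one uniform scale per row
from (0.9, 1.1) and one uniform offset from (−0.01, 0.01); originals are
retained and targets untouched. The split is a seeded shuffle into
⌊0.7n⌋ / ⌊0.2n⌋ / remainder; optional grouping keeps all leaves of a plant in
one partition (greedy largest-deficit assignment, warning when group sizes
make the ratio unattainable within one group).

## Regressors

All four networks are NumPy with manual backpropagation and Adam
(lr 3e-3, batch 32, ≤ 400 epochs, early stopping on validation loss with
patience 60 and best-weight restoration, gradient-norm clipping at 5).
Features and target are z-scored by training-set statistics only (a test
asserts the absence of leakage). MLP and FCNN are both dense; the
distinction is interpreted as compact (128-64) vs deeper/wider (256-128-64).
RNN (tanh, hidden 64) and LSTM (standard gates, forget bias 1, hidden 64)
consume the feature vector through an invertible band-major layout: 6 steps
of 80 values, each step one band's mean followed by its 79 texture features;
generic vectors zero-pad to a chunk multiple. Targets are modelled one at a
time. Seeded end to end: identical seeds give identical weights and
predictions.

## Recovery experiment (the acceptance workload)

n = 300 laboratory leaves at the default 256×192 canvas, imaging noise
σ = 0.005, illumination jitter 0.02, seed fixed; 7:2:1 split; nitrogen via
MLP and LSTM on all 480 features and LSTM on the 6 spectral means alone;
nicotine via LSTM on both feature sets. Expected structure: nitrogen is
recoverable from either feature set (R² ≳ 0.95) with a modest fusion gain;
nicotine is recoverable *only* with texture (spectral-only R² ≈ 0) — the
structural demonstration that texture features complement spectral means.
The nitrogen fusion margin is small because six-band ratios largely cancel
the illumination gain; the nicotine margin is guaranteed by construction.
Problem sizes (300 leaves, 256×192 canvas, 96×72 canvases for the
dataset-accounting checks) keep the whole suite around a minute of compute
while leaving every statistical check well-powered.

## Known limitations

* The detector itself is not trained here; segmentation quality on real
  imagery is outside what the synthetic masks can certify.
* Bands are assumed co-registered (true by construction for the generator);
  cross-lens registration of real captures is out of scope, as are
  vignetting/irradiance corrections and two-point calibration.
* The texture bank's discriminative power on real leaves depends on venation
  being resolvable at the working resolution; the generator's sinusoidal
  veins are an idealization.
* MLP/FCNN hyperparameters and the sequence layout are declared conventions,
  not tuned optima.
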