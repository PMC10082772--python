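# Methods

## Problem setting

Live volumetric OCT acquires B-scans (2D slabs of consecutive A-scans) at MHz
A-scan rates. Speed costs SNR, and laser speckle adds strong, structured
fluctuation on top. Clean targets for supervised denoising do not exist in a
live setting, and multi-frame averaging is ruled out by motion and latency.
This package implements a self-supervised *blind-spot* denoiser that trains on
single noisy B-scans, plus the streaming buffer pipeline that applies it
inside a reconstruction data path, and evaluates everything on synthetic
phantoms with known ground truth.

The model of the data is additive in the log domain: a pixel is v = s + n
with deterministic signal s and zero-mean noise n (speckle is multiplicative
in intensity and becomes additive after logarithmic scaling; mean-preserving
frame averaging motivates E[n] = 0). A network trained to predict a pixel
whose value (and correlated neighbourhood) is hidden from its input can at
best learn E[v | context] = s: the noise is unpredictable, so the regression
target's noise averages out. All processing happens after log scaling and
*before* black-level subtraction, so the denoiser sees the full dynamic range
and is independent of display settings.

## Structured masking with continuous-strip replacement

Pixel-wise blind spots fail when noise is spatially correlated: neighbours
leak the hidden value. In point-scanning OCT the correlation is mainly axial
(along an A-scan), so each sampled center pixel is extended to a 7x1 axial
strip (center plus three pixels on either side). The defaults are:

| parameter         | default | meaning                                        |
|-------------------|---------|------------------------------------------------|
| `center_fraction` | 0.001   | fraction of pixels sampled as blind-spot centers |
| `mask_shape`      | (7, 1)  | axial x lateral strip extent                   |
| `max_offset`      | 5       | Chebyshev radius of the replacement source     |

Instead of filling the strip with random values, the whole strip is replaced
by the *continuous* strip at a random offset drawn uniformly from the
(2*5+1)^2 square, zero offset allowed, so the masked region still looks like
plausible image content. Centers are sampled uniformly without replacement
among positions whose strip fits in the patch; offsets whose source strip
would leave the patch are redrawn. The loss is evaluated at center pixels
only, against the original (pre-masking) values. Overlapping strips read from
the pristine input, so the masked patch is a pure function of (input, plan).

## Network family

A depth-2 U-Net, deliberately light: n filters in the uppermost level, 2n in
the middle, 4n in the bottleneck; 2x2/stride-2 max pooling down, 2x2/stride-2
transposed convolutions up. Each 3x3 convolution is size-preserving and
followed by batch normalization and ReLU (the fused unit of the deployed
network); the output head is a linear 1x1 projection. Two switches ablate the
connections responsible for high-frequency checkerboard artifacts in
blind-spot U-Nets: `residual` (global input-to-output addition) and
`top_skip` (uppermost encoder-decoder concatenation). The lower skip is
always present.

The bottleneck holds a *single* conv block. With two, the theoretical
receptive field would be 44 px and would overrun the 41x41 budget that the
deployment pipeline's 20-A-scan padding covers; with one it is 36x36
(half-width 18 <= 20). `measure_receptive_field` confirms this empirically by
backpropagating from one central output pixel and bounding the nonzero input
gradient footprint, maximized over several weight draws (ReLU/arg-max gating
can hide parts of the footprint in any single draw); the measured extent for
the default variants is 33x33.

The layers themselves (convolutions, pooling, transposed convolutions, batch
norm, ReLU, Adam) are a small self-contained CPU engine with hand-written
backpropagation (`octdenoise.nn`), NCHW float32, im2col + BLAS matmul in
training. Inference-path convolutions instead use an `einsum` contraction
whose per-pixel accumulation order does not depend on the image width; this
is what makes sub-buffer and whole-buffer inference agree *bitwise* away from
the outer padding margins (BLAS kernels change with matrix shape and would
leave ~1e-7 discrepancies).

## Training regime

An epoch is a fixed number of steps; each step samples random patches
(uniform top-left corners, overlaps allowed), augments, masks, and minimizes
the masked MSE with Adam. Two augmentations:

* lateral flip with probability 0.5 (reverses the scan direction, preserves
  A-scan statistics);
* intensity-range remapping emulating different black-level / dynamic-range
  settings: two draws from N(0, 0.25) clipped to [-1, 1] are rectified so a
  bound only moves inward (b_lo = max(0, d_lo), b_hi = 1 + min(0, d_hi)),
  leaving each bound unchanged with probability 1/2 and the whole image in
  1/4 of the cases; values map linearly from [0, 1] to [b_lo, b_hi].

The validation loss is a masked MSE over a deterministic tiling of the
validation images with mask plans from a fixed seed, so it is a deterministic
function of the weights. The learning rate halves when no strictly lower
validation loss appears for 10 consecutive epochs (counter resets on
improvement and after each halving; floor 1e-7, both unstated upstream and
chosen conventionally), and the weights of the best validation epoch are
exported. Adam moments are the conventional (0.9, 0.999).

Two profiles ship:

* **full scale**: 300 epochs x 600 steps, batch 128, 200x200 patches,
  initial lr 2e-5 — the full regime, impractical without a GPU;
* **desk scale** (default): 30 epochs x 100 steps, batch 16, 64x64 patches,
  initial lr 1e-2. With 60x fewer updates and ~100x fewer loss-carrying
  center pixels per step, the full-scale step size stalls far from the
  blind-spot optimum; 1e-2 was selected on the constant-signal toy problem
  (below) as the step size at which the converged validation loss reaches the
  noise-variance floor, and is kept fixed everywhere the desk profile is used.

Everything is reproducible from a single seed (weight init, patch sampling,
augmentation, masking, validation masks).

## Synthetic phantoms

The generator emulates log-scaled layered-tissue B-scans: a dark background
(floor 0.1), a bright 3-px membrane at the tissue surface, and 6 (by default)
piecewise-constant reflectivity layers separated by sum-of-sinusoid wavy
boundaries, strictly ordered at every column (the total waviness is capped at
45% of the layer spacing so ordering holds on any image size). Values live in
[0, 1]; 8-bit export clips and rounds half away from zero.

Noise is a zero-mean Gaussian field in the log domain: white noise smoothed
by a separable Gaussian kernel (sigma_ax = 1.5 px axially, sigma_lat = 0),
rescaled by the exact discrete-kernel factor to a marginal sigma of 0.1, and
mean-centered. Smoothing uses circular convolution, so the field is
stationary and its axial autocorrelation follows the closed form
exp(-k^2/(4 sigma_ax^2)) — negligible beyond +-3 px, which is exactly the
regime the 7x1 mask is designed to hide. The choice of a Gaussian log-domain
model (rather than Rayleigh/exponential intensity speckle) matches the
working assumption of the method and makes the zero-mean property exact.

Datasets carry disjoint-seeded train/val/eval splits; eval items additionally
hold the clean truth, a 100-frame average reference (no registration needed:
phantoms are static), and a programmatic ROI set of 14 foreground rectangles
placed inside layers plus one background rectangle above the surface,
validated for bounds and disjointness. What the phantoms deliberately do not
model: real speckle's intensity statistics, lateral noise correlation from
dense A-scan sampling, saturation/hyper-reflection artifacts, motion, and
scan-geometry distortion — so green tests here show the machinery is correct
and the method behaves as the theory predicts on data satisfying its
assumptions, not that clinical image quality is reproduced.

## Deployment pipeline

A reconstruction buffer is split laterally into 4 sub-buffers that run as the
4 channels of one network whose weights were replicated per channel with all
cross-channel entries set to zero (pseudo-batching). Batch-norm statistics
are frozen before replication, so channel independence is exact. Each
sub-buffer is padded by 20 A-scans per side: outer edges replicate the
first/last A-scan, interior cuts use the true continuation; after inference
the overlap is discarded. Given pad >= the receptive half-width (18), the
recombined buffer equals whole-buffer inference exactly away from the two
outer margins. Geometry constraints are validated rather than silently
patched: the lateral size must divide by the sub-buffer count and each core
width by 4 (pooling-grid alignment), and the pad must be even.

Half-precision inference mirrors the fused deployment path: batch norm is
folded into the preceding convolution, weights and activations are stored as
float16, and sums accumulate in float32 inside each fused block. The
Gaussian reference filter is a single 2D convolution with an isotropic
kernel truncated at two standard deviations (21x21 for sigma = 5),
renormalized to sum 1, with edge replication. Black-level subtraction is
max(0, image - level), applied after denoising.

## Evaluation protocol

PSNR = 10 log10(R^2 / MSE) with R = 255 on the 8-bit scale (identical images
report +inf and are excluded from aggregation with a warning); SSIM uses an
11x11 Gaussian window (sigma 1.5, K1 = 0.01, K2 = 0.03), recorded in every
report; CNR averages (mu_f - mu_b)/sqrt(var_f + var_b) over the 14
foreground ROIs against the single background ROI, with population (N)
variance inside the formula. PSNR/SSIM are computed on a central crop,
CNR on the full image. Aggregates report the mean and twice the *sample*
(n-1) standard deviation, all images weighted equally. The 2D noise
autocorrelation (FFT-based, circular, lag (0,0) normalized to 1) closes the
loop on the noise model.

## Reference experiments and measured numbers

`octdenoise.experiments` pins the study conditions used by the test suite
and the acceptance script (all problem sizes are the package's own choices):

* **Desk run** — default phantoms, 10/2/10 split; U-Net(no residual, no top
  skip, n=4) trained with the desk profile. Held-out against the clean
  truth: PSNR 24.6 dB vs 20.0 dB for the noisy input (gain +4.6 dB), SSIM
  0.70 vs 0.31, CNR 10.7 vs 3.7; half- vs single-precision inference differs
  by 0.03 gray values (8-bit scale) in median.
* **Blind-spot floor** — constant 0.5 + iid sigma = 0.1 noise, small net
  (n=2), 12 x 50 steps, ~640 fixed validation centers: converged validation
  masked-MSE within 20% of the 0.01 noise-variance floor (the sampling error
  of the estimate itself is a few percent, which is why the validation split
  is large).
* **Receptive field** — measured 33x33 for all default n=4 variants,
  theoretical 36x36, bound 41x41.

## Numerical choices and edge cases

* Internal range [0, 1]; no clipping during processing, only at 8-bit export.
* Patch/image sides must divide by 4 (two poolings); `predict_image`
  edge-pads odd sizes and crops back.
* Mask plans with zero centers are legal empty plans; an all-empty validation
  tiling is an error (undefined mean).
* Batch-norm: momentum 0.1, eps 1e-5, population batch variance; running
  statistics are used at validation and inference.
* CNR with zero variance in both ROIs of a pair, constant fields in the
  autocorrelation, and empty evaluation sets raise rather than return
  sentinels.
* PSNR of identical images is +inf by convention, never a capped number.

## Known limitations

* The phantom noise model is Gaussian in the log domain with purely axial
  correlation; real speckle deviates from both.
* Desk-scale training is a convergence-limited surrogate: scores are far
  below what the full schedule reaches on real data, and the n=8..32 /
  full-scale configurations, while available, are untested at scale here.
* The CPU engine is single-threaded NumPy; it is meant for correctness and
  desk-scale experiments, not throughput. No GPU, ONNX or TensorRT path
  exists, and wall-clock performance claims are out of scope.
* Real deployments interleave denoising with reconstruction steps (background
  subtraction, dispersion, FFT) that are not modelled; the pipeline here
  starts at log-scaled buffers.
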