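# octdenoise

Self-supervised blind-spot denoising for OCT B-scans: structured
Noise2Void-style masking with continuous-strip replacement, a light-weight
depth-2 U-Net family with switchable residual / top-level skip connections,
and the streaming buffer split/pad/pseudo-batch inference pipeline used to
run such a network inside a real-time reconstruction data path. Everything is
exercised end to end on synthetic layered-tissue speckle phantoms with known
ground truth.

**Who it is for.** Researchers in OCT / biomedical image analysis who want a
tested, reproducible reference implementation of blind-spot denoising under
*structured* (axially correlated) noise — without paired or clean training
data — plus the evaluation protocol (PSNR, SSIM, ROI-based CNR, noise
autocorrelation) to measure it.

## The method in brief

A log-scaled OCT pixel is modelled as v = s + n with deterministic signal s
and zero-mean, possibly axially correlated noise n. A network that must
predict a pixel from its surroundings — with the pixel *and* its correlated
axial neighbours hidden — can only learn

    E[v | context] = E[s] + E[n] = s,

so training on single noisy images with a masked MSE yields a denoiser.
Masking samples 0.1% of pixels as centers, extends each to a 7x1 axial strip,
and replaces the strip with a continuous strip from a random offset within
+-5 pixels (zero allowed); the loss is evaluated at the centers only, against
the original values. The network is a depth-2 U-Net (n, 2n, 4n channels) in
four variants: with/without the global residual connection (r) and the
top-level skip (t); omitting both — U-Net(not r, not t) — suppresses
high-frequency artifacts and is the deployment default. For streaming
inference a buffer is split into 4 sub-buffers, padded by 20 A-scans per side
(edge replication outside, true continuation at interior cuts — the padding
covers the network's 41x41 receptive-field budget), run as 4 channels of a
replicated-weight network with zeroed cross-channel entries, and recombined
seam-free.

## Worked example

```python
from octdenoise.experiments import (desk_dataset, train_desk_model,
                                    evaluate_desk_model)

dataset = desk_dataset(seed=7)                   # 10 train / 2 val / 10 eval
trained = train_desk_model(dataset, seed=7)      # U-Net(¬r,¬t), n=4, ~5 min CPU
result = evaluate_desk_model(trained.model, dataset)

print(f"PSNR denoised {result.report.aggregate['psnr'].iloc[0]:.2f} dB "
      f"vs noisy {result.noisy_report.aggregate['psnr'].iloc[0]:.2f} dB "
      f"(gain {result.psnr_gain_db:+.2f} dB)")
print(f"SSIM {result.report.aggregate['ssim'].iloc[0]:.3f}, "
      f"CNR {result.report.aggregate['cnr'].iloc[0]:.2f}")
print(f"half-precision median |diff| {result.half_median_gray:.3f} gray")
```

prints (sigma = 0.1 log-domain phantom noise, scores on the 0–255 scale
against the clean truth, mean over the 10 held-out phantoms):

```
PSNR denoised 24.59 dB vs noisy 19.96 dB (gain +4.63 dB)
SSIM 0.700, CNR 10.72
half-precision median |diff| 0.028 gray
```

Denoising raises PSNR by ~4.6 dB, more than doubles SSIM (0.31 for the noisy
input) and lifts the contrast-to-noise ratio from 3.7 to 10.7, while half-
and single-precision inference agree to a few hundredths of a gray value.

A scikit-learn-style estimator wraps the same machinery:

```python
from octdenoise import BlindSpotDenoiser
est = BlindSpotDenoiser(n=4, residual=False, top_skip=False, random_state=7)
est.fit(noisy_images)            # self-supervised: no clean targets
denoised = est.transform(noisy_images)
```

and a CLI drives the full workflow from the shell:

```
octdenoise simulate --out data --seed 7
octdenoise train    --data data --out run --seed 7
octdenoise denoise  --model run/model.npz --data data --out run/denoised
octdenoise evaluate --data data --denoised run/denoised --out run/report.csv
octdenoise rfcheck --n 4
octdenoise benchmark
```

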