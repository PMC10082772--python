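"""Canonical reduced-scale experiment: phantoms -> training -> evaluation.

These helpers pin the study conditions used throughout the package's own
checks: the default phantom generator, a 10/2/10 train/val/eval split, the
reduced-scale training profile, and the PSNR/SSIM/CNR scoring of the result
against the clean phantom truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import MetricReport, evaluate, psnr
from .network import NetSpec, UNet, build_unet, predict_image
from .phantom import PhantomDataset, PhantomSpec, make_dataset
from .training import TrainedModel, desk_profile, train_model


def desk_dataset(seed: int, n_train: int = 10, n_val: int = 2, n_eval: int = 10,
                 m_avg: int = 100, spec: PhantomSpec | None = None) -> PhantomDataset:
    """Default phantom dataset for reduced-scale experiments."""
    spec = spec or PhantomSpec()
    return make_dataset(n_train, n_val, n_eval, spec, seed=seed, m_avg=m_avg)


def train_desk_model(dataset: PhantomDataset, seed: int, n: int = 4,
                     residual: bool = False, top_skip: bool = False,
                     **overrides) -> TrainedModel:
    """Train a U-Net variant with the reduced-scale profile on a dataset."""
    config = desk_profile(seed=seed, **overrides)
    model = build_unet(NetSpec(n=n, residual=residual, top_skip=top_skip, seed=seed))
    train_images = [s.noisy.pixels for s in dataset.train]
    val_images = [s.noisy.pixels for s in dataset.val]
    return train_model(model, train_images, val_images, config)


@dataclass
class DeskEvaluation:
    """Held-out scores of a trained model on the phantom eval split."""

    report: MetricReport
    noisy_report: MetricReport
    psnr_gain_db: float          # mean PSNR(denoised) - mean PSNR(noisy)
    half_median_gray: float      # median |fp16 - fp32| on the 0-255 scale


def evaluate_desk_model(model: UNet, dataset: PhantomDataset,
                        reference: str = "clean") -> DeskEvaluation:
    """Score denoised vs noisy eval frames and the half-precision fidelity.

    PSNR/SSIM are computed on the 0-255 scale against the chosen reference
    (``clean`` truth or the ``avg`` multi-frame average), on a central crop;
    CNR uses each item's 14+1 ROI set.
    """
    items = dataset.eval
    if not items:
        raise ValueError("dataset has no eval split")
    refs, noisy, denoised, rois, half_diffs = [], [], [], [], []
    for item in items:
        ref_img = item.sample.clean.pixels if reference == "clean" else item.average.pixels
        refs.append(ref_img * 255.0)
        noisy.append(item.sample.noisy.pixels * 255.0)
        single = predict_image(model, item.sample.noisy.pixels)
        half = predict_image(model, item.sample.noisy.pixels, half=True)
        denoised.append(single * 255.0)
        half_diffs.append(np.abs(single - half).ravel() * 255.0)
        rois.append(item.sample.rois)
    h, w = refs[0].shape
    crop = (h // 8, h - h // 8, w // 8, w - w // 8)
    report = evaluate(denoised, refs, rois=rois, crop=crop)
    noisy_report = evaluate(noisy, refs, rois=rois, crop=crop)
    gain = (float(report.aggregate["psnr"].iloc[0])
            - float(noisy_report.aggregate["psnr"].iloc[0]))
    half_median = float(np.median(np.concatenate(half_diffs)))
    return DeskEvaluation(report=report, noisy_report=noisy_report,
                          psnr_gain_db=gain, half_median_gray=half_median)


def blind_spot_floor_experiment(seed: int, noise_sigma: float = 0.1,
                                n_train: int = 8, n_val: int = 40) -> tuple[float, float]:
    """Blind-spot optimum on constant signal + iid noise.

    Returns (converged validation masked-MSE, noise variance).  With no
    deterministic structure beyond the constant level, the best blind-spot
    prediction of a pixel is the constant, so the validation loss floor is
    Var(n) = noise_sigma**2.  The validation split is large (~640 fixed
    blind-spot centers) so that the sampling error of the loss estimate is a
    few percent of the floor.
    """
    rng = np.random.default_rng(seed)
    shape = (64, 256)
    images = [0.5 + noise_sigma * rng.standard_normal(shape)
              for _ in range(n_train + n_val)]
    train_images, val_images = images[:n_train], images[n_train:]
    config = desk_profile(epochs=12, steps_per_epoch=50, batch_size=8,
                          initial_lr=1e-2, seed=seed)
    model = build_unet(NetSpec(n=2, seed=seed))
    trained = train_model(model, train_images, val_images, config)
    return float(trained.history["val_loss"].min()), noise_sigma ** 2
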