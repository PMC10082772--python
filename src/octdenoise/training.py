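"""Self-supervised training loop for the blind-spot denoiser.

An epoch is a fixed number of steps; each step extracts random patches from
the training images, augments them (random lateral flip; random intensity
range remapping emulating different black-level / dynamic-range settings),
masks blind-spot strips, and minimizes the MSE between the prediction and the
*original* (pre-masking) values at the center pixels only.  Adam drives the
updates; the learning rate is halved whenever the validation loss plateaus,
and the weights with the lowest validation loss are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .masking import MaskConfig, MaskPlan, apply_mask, build_mask_plan
from .network import NetSpec, UNet, copy_model
from .nn import Adam


@dataclass
class TrainConfig:
    """Training hyper-parameters (full-scale defaults; see desk_profile())."""

    epochs: int = 300
    steps_per_epoch: int = 600
    batch_size: int = 128
    patch_size: tuple[int, int] = (200, 200)
    initial_lr: float = 2e-5
    plateau_patience: int = 10
    lr_factor: float = 0.5
    lr_floor: float = 1e-7
    flip_prob: float = 0.5
    jitter_sigma: float = 0.25
    jitter_clip: tuple[float, float] = (-1.0, 1.0)
    mask: MaskConfig = field(default_factory=MaskConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.steps_per_epoch, self.batch_size) < 0:
            raise ValueError("counts must be >= 0")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must be in (0, 1)")
        if self.patch_size[0] % 4 or self.patch_size[1] % 4:
            raise ValueError("patch dims must be divisible by 4")


def desk_profile(**overrides) -> TrainConfig:
    """Reduced-scale profile for CPU-time experiments.

    Far fewer updates than the full schedule, compensated by a larger Adam
    step size (1e-2, without which 3000 sparse-gradient updates do not reach
    the blind-spot optimum); everything else (masking, augmentations,
    scheduler) is identical.
    """
    cfg = dict(epochs=30, steps_per_epoch=100, batch_size=16,
               patch_size=(64, 64), initial_lr=1e-2)
    cfg.update(overrides)
    return TrainConfig(**cfg)


def augment(patch: np.ndarray, rng: np.random.Generator,
            config: TrainConfig) -> np.ndarray:
    """Random lateral flip + random intensity-range remapping.

    The remap draws two clipped Gaussians and rectifies them so that each
    bound only ever moves inward: b_lo = max(0, d_lo), b_hi = 1 + min(0, d_hi).
    Each bound is therefore unchanged with probability 1/2 and the whole image
    with probability 1/4.  Values are mapped linearly from [0, 1] to
    [b_lo, b_hi].
    """
    out = np.asarray(patch, dtype=np.float64)
    if rng.random() < config.flip_prob:
        out = out[:, ::-1]
    lo_c, hi_c = config.jitter_clip
    while True:
        d_lo = float(np.clip(rng.normal(0.0, config.jitter_sigma), lo_c, hi_c))
        d_hi = float(np.clip(rng.normal(0.0, config.jitter_sigma), lo_c, hi_c))
        b_lo = max(0.0, d_lo)
        b_hi = 1.0 + min(0.0, d_hi)
        if b_lo < b_hi:
            break
    if b_lo == 0.0 and b_hi == 1.0:
        return np.ascontiguousarray(out)
    return np.ascontiguousarray(b_lo + out * (b_hi - b_lo))


def masked_mse(pred: np.ndarray, target: np.ndarray, loss_mask: np.ndarray) -> float:
    """Mean squared error over the masked (center) pixels only."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape or pred.shape != loss_mask.shape:
        raise ValueError("pred/target/loss_mask shapes must match")
    if not loss_mask.any():
        raise ValueError("empty loss mask: masked MSE is undefined")
    d = pred[loss_mask] - target[loss_mask]
    return float(np.mean(d * d))


class PlateauScheduler:
    """Halve the learning rate after ``patience`` epochs without a strictly
    lower validation loss; the counter resets on improvement and after each
    reduction; the rate never drops below ``floor``."""

    def __init__(self, initial_lr: float, patience: int = 10,
                 factor: float = 0.5, floor: float = 1e-7) -> None:
        self.lr = float(initial_lr)
        self.patience = patience
        self.factor = factor
        self.floor = floor
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, val_loss: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs >= self.patience:
                self.lr = max(self.floor, self.lr * self.factor)
                self.bad_epochs = 0
        return self.lr


@dataclass
class TrainedModel:
    spec: NetSpec
    model: UNet                       # weights of the best validation epoch
    history: pd.DataFrame             # epoch, train_loss, val_loss, lr
    best_epoch: int


def sample_patch(image: np.ndarray, patch_size: tuple[int, int],
                 rng: np.random.Generator) -> np.ndarray:
    h, w = image.shape
    ph, pw = patch_size
    if ph > h or pw > w:
        raise ValueError(f"patch {patch_size} larger than image {image.shape}")
    r = int(rng.integers(0, h - ph + 1))
    c = int(rng.integers(0, w - pw + 1))
    return image[r:r + ph, c:c + pw]


def _batch_step(model: UNet, optimizer: Adam, images: list[np.ndarray],
                config: TrainConfig, rng: np.random.Generator) -> float:
    ph, pw = config.patch_size
    xs = np.empty((config.batch_size, 1, ph, pw), dtype=np.float32)
    ts = np.empty_like(xs)
    masks = np.zeros((config.batch_size, 1, ph, pw), dtype=bool)
    for b in range(config.batch_size):
        img = images[int(rng.integers(0, len(images)))]
        patch = augment(sample_patch(img, config.patch_size, rng), rng, config)
        plan = build_mask_plan(patch.shape, config.mask, rng)
        xs[b, 0] = apply_mask(patch, plan)
        ts[b, 0] = patch
        masks[b, 0] = plan.loss_mask
    n_masked = int(masks.sum())
    if n_masked == 0:
        raise ValueError("no blind-spot centers in batch; raise center_fraction")
    pred = model.forward(xs, train=True)
    diff = np.where(masks, pred - ts, 0.0).astype(np.float32)
    loss = float((diff[masks] ** 2).mean())
    grad = (2.0 / n_masked) * diff
    optimizer.zero_grad()
    model.backward(grad)
    optimizer.step()
    return loss


def validate(model: UNet, val_images: list[np.ndarray], config: TrainConfig,
             fixed_seed: int) -> float:
    """Masked MSE over a deterministic tiling of the validation images.

    Mask plans are drawn from ``fixed_seed`` alone, so the result is a
    deterministic function of the weights.
    """
    if not val_images:
        raise ValueError("empty validation set")
    rng = np.random.default_rng(fixed_seed)
    ph, pw = config.patch_size
    sq_sum, count = 0.0, 0
    for img in val_images:
        h, w = img.shape
        for r in range(0, h - ph + 1, ph):
            for c in range(0, w - pw + 1, pw):
                patch = np.ascontiguousarray(img[r:r + ph, c:c + pw])
                plan = build_mask_plan(patch.shape, config.mask, rng)
                if len(plan.centers) == 0:
                    continue
                x = apply_mask(patch, plan)[None, None].astype(np.float32)
                pred = model.forward(x, train=False)[0, 0]
                d = pred[plan.loss_mask] - patch[plan.loss_mask]
                sq_sum += float((d * d).sum())
                count += d.size
    if count == 0:
        raise ValueError("validation tiling produced no masked centers")
    return sq_sum / count


def train_model(model: UNet, train_images: list[np.ndarray],
                val_images: list[np.ndarray], config: TrainConfig,
                verbose: bool = False) -> TrainedModel:
    """Run the full self-supervised schedule; reproducible from config.seed."""
    if not train_images and config.epochs > 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    val_seed = int(np.random.default_rng(config.seed + 1).integers(2 ** 31))
    optimizer = Adam(model.layers(), lr=config.initial_lr)
    scheduler = PlateauScheduler(config.initial_lr, config.plateau_patience,
                                 config.lr_factor, config.lr_floor)
    history = []
    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    for epoch in range(1, config.epochs + 1):
        losses = [_batch_step(model, optimizer, train_images, config, rng)
                  for _ in range(config.steps_per_epoch)]
        val_loss = validate(model, val_images, config, val_seed)
        lr_now = optimizer.lr
        optimizer.lr = scheduler.step(val_loss)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_loss": val_loss, "lr": lr_now})
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        if verbose:
            import logging
            logging.getLogger(__name__).info(
                "epoch %d train %.3g val %.3g lr %.3g",
                epoch, history[-1]["train_loss"], val_loss, lr_now)
    best = copy_model(model)
    best.load_state_dict(best_state)
    return TrainedModel(spec=model.spec, model=best,
                        history=pd.DataFrame(
                            history, columns=["epoch", "train_loss", "val_loss", "lr"]),
                        best_epoch=best_epoch)
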