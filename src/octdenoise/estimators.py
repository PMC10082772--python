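"""Scikit-learn style estimators wrapping the blind-spot denoiser.

``BlindSpotDenoiser`` is a transformer: ``fit`` runs the self-supervised
schedule on a stack of noisy B-scans (no clean targets), ``transform`` denoises
images with the best-validation weights.  ``GaussianDenoiser`` is the stateless
reference filter.  Both compose with sklearn pipelines and ``clone``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .masking import MaskConfig
from .network import NetSpec, UNet, build_unet, measure_receptive_field, predict_image
from .pipeline import gaussian_baseline
from .training import TrainConfig, train_model


def _as_image_list(X) -> list[np.ndarray]:
    if isinstance(X, np.ndarray) and X.ndim == 2:
        return [np.asarray(X, dtype=np.float64)]
    imgs = [np.asarray(x, dtype=np.float64) for x in X]
    for img in imgs:
        if img.ndim != 2:
            raise ValueError("expected 2D images (axial x lateral)")
    return imgs


class BlindSpotDenoiser(TransformerMixin, BaseEstimator):
    """Self-supervised blind-spot denoiser for log-scaled B-scans.

    Parameters mirror the architecture switches (``n``, ``residual``,
    ``top_skip``), the structured masking (``center_fraction``, ``mask_height``,
    ``max_offset``) and the training schedule.  Defaults are the reduced-scale
    profile; pass ``profile="full"`` for the full schedule.

    Attributes (after ``fit``): ``model_`` (trained network, best validation
    weights), ``history_`` (per-epoch losses and learning rate),
    ``best_epoch_``, ``receptive_field_``.
    """

    def __init__(self, n=4, residual=False, top_skip=False,
                 epochs=30, steps_per_epoch=100, batch_size=16,
                 patch_size=(64, 64), learning_rate=1e-2,
                 plateau_patience=10, lr_factor=0.5, lr_floor=1e-7,
                 flip_prob=0.5, jitter_sigma=0.25,
                 center_fraction=0.001, mask_height=7, max_offset=5,
                 validation_fraction=0.2, profile=None, random_state=0):
        self.n = n
        self.residual = residual
        self.top_skip = top_skip
        self.epochs = epochs
        self.steps_per_epoch = steps_per_epoch
        self.batch_size = batch_size
        self.patch_size = patch_size
        self.learning_rate = learning_rate
        self.plateau_patience = plateau_patience
        self.lr_factor = lr_factor
        self.lr_floor = lr_floor
        self.flip_prob = flip_prob
        self.jitter_sigma = jitter_sigma
        self.center_fraction = center_fraction
        self.mask_height = mask_height
        self.max_offset = max_offset
        self.validation_fraction = validation_fraction
        self.profile = profile
        self.random_state = random_state

    def _train_config(self) -> TrainConfig:
        mask = MaskConfig(center_fraction=self.center_fraction,
                          mask_shape=(self.mask_height, 1),
                          max_offset=self.max_offset)
        if self.profile == "full":
            return TrainConfig(mask=mask, seed=self.random_state)
        return TrainConfig(epochs=self.epochs, steps_per_epoch=self.steps_per_epoch,
                           batch_size=self.batch_size,
                           patch_size=tuple(self.patch_size),
                           initial_lr=self.learning_rate,
                           plateau_patience=self.plateau_patience,
                           lr_factor=self.lr_factor, lr_floor=self.lr_floor,
                           flip_prob=self.flip_prob, jitter_sigma=self.jitter_sigma,
                           mask=mask, seed=self.random_state)

    def net_spec(self) -> NetSpec:
        return NetSpec(n=self.n, residual=self.residual, top_skip=self.top_skip,
                       seed=self.random_state)

    def fit(self, X, y=None, X_val=None):
        """Train on noisy images; ``y`` is ignored (self-supervised).

        If ``X_val`` is not given, the last ``validation_fraction`` of the
        images (at least one) is held out for the plateau schedule and
        best-epoch selection.
        """
        images = _as_image_list(X)
        if X_val is not None:
            val = _as_image_list(X_val)
        else:
            n_val = max(1, int(round(self.validation_fraction * len(images))))
            if len(images) <= n_val:
                raise ValueError("not enough images to hold out a validation split")
            images, val = images[:-n_val], images[-n_val:]
        config = self._train_config()
        model = build_unet(self.net_spec())
        trained = train_model(model, images, val, config)
        self.model_ = trained.model
        self.history_ = trained.history
        self.best_epoch_ = trained.best_epoch
        self.receptive_field_ = self.model_.receptive_field()
        return self

    def transform(self, X, half: bool = False):
        if not hasattr(self, "model_"):
            raise RuntimeError("BlindSpotDenoiser is not fitted")
        images = _as_image_list(X)
        out = [predict_image(self.model_, img, half=half) for img in images]
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return out[0]
        return out

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        tags.requires_fit = True
        return tags


class GaussianDenoiser(TransformerMixin, BaseEstimator):
    """Stateless Gaussian reference filter (truncated at two sigmas)."""

    def __init__(self, sigma: float = 5.0):
        self.sigma = sigma

    def fit(self, X, y=None):
        self.fitted_ = True
        return self

    def transform(self, X):
        images = _as_image_list(X)
        out = [gaussian_baseline(img, sigma=self.sigma) for img in images]
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return out[0]
        return out

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.two_d_array = False
        tags.requires_fit = False
        return tags
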