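"""Structured blind-spot masking with continuous-strip replacement.

A fraction of pixels is sampled as blind-spot centers; each center is extended
to an axial strip (default 7x1, hiding the three axially adjacent pixels on
either side, which carry correlated speckle), and the whole strip is replaced
by an intact strip copied from a random nearby offset.  Copying a continuous
strip — rather than filling with independent random values — keeps the masked
neighborhood statistically similar to real image content.  The training loss
is evaluated at the center pixels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MaskConfig:
    """Blind-spot sampling parameters.

    center_fraction : fraction of image pixels sampled as centers (0.1% default).
    mask_shape : (axial, lateral) strip extent; the axial extent must be odd.
    max_offset : Chebyshev radius of the replacement-source offset (0 allowed).
    """

    center_fraction: float = 0.001
    mask_shape: tuple[int, int] = (7, 1)
    max_offset: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.center_fraction <= 1.0:
            raise ValueError("center_fraction must be in [0, 1]")
        if self.mask_shape[0] % 2 == 0 or self.mask_shape[1] % 2 == 0:
            raise ValueError("mask extents must be odd")
        if self.max_offset < 0:
            raise ValueError("max_offset must be >= 0")


@dataclass
class MaskPlan:
    """Concrete masking realization for one patch shape."""

    shape: tuple[int, int]
    mask_shape: tuple[int, int]
    centers: np.ndarray          # (M, 2) int rows/cols
    offsets: np.ndarray          # (M, 2) int (d_row, d_col)
    loss_mask: np.ndarray        # bool (H, W), True exactly at centers

    def strips(self) -> list[np.ndarray]:
        """Per center, the (K, 2) array of masked coordinates."""
        ha, hl = self.mask_shape[0] // 2, self.mask_shape[1] // 2
        out = []
        for r, c in self.centers:
            rr, cc = np.meshgrid(np.arange(r - ha, r + ha + 1),
                                 np.arange(c - hl, c + hl + 1), indexing="ij")
            out.append(np.stack([rr.ravel(), cc.ravel()], axis=1))
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "center_row": self.centers[:, 0], "center_col": self.centers[:, 1],
            "d_row": self.offsets[:, 0], "d_col": self.offsets[:, 1]})

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_mask_plan(shape: tuple[int, int], config: MaskConfig,
                    rng: np.random.Generator) -> MaskPlan:
    """Sample blind-spot centers and replacement offsets for an image shape.

    Centers are uniform without replacement over the positions whose strip fits
    entirely inside the image; offsets are uniform on the Chebyshev square,
    redrawn per center until the source strip is also in bounds.
    """
    h, w = shape
    ha, hl = config.mask_shape[0] // 2, config.mask_shape[1] // 2
    rows_valid = h - 2 * ha
    cols_valid = w - 2 * hl
    if rows_valid < 1 or cols_valid < 1 or h < config.mask_shape[0] + config.max_offset:
        raise ValueError(f"shape {shape} cannot host a {config.mask_shape} strip "
                         f"with max_offset {config.max_offset}")
    n_centers = int(round(config.center_fraction * h * w))
    if n_centers == 0:
        return MaskPlan(shape, config.mask_shape,
                        centers=np.empty((0, 2), dtype=int),
                        offsets=np.empty((0, 2), dtype=int),
                        loss_mask=np.zeros(shape, dtype=bool))
    n_centers = min(n_centers, rows_valid * cols_valid)
    flat = rng.choice(rows_valid * cols_valid, size=n_centers, replace=False)
    centers = np.stack([flat // cols_valid + ha, flat % cols_valid + hl], axis=1)

    m = config.max_offset
    offsets = np.zeros((n_centers, 2), dtype=int)
    if m > 0:
        for i, (r, c) in enumerate(centers):
            while True:
                dr = rng.integers(-m, m + 1)
                dc = rng.integers(-m, m + 1)
                if (ha <= r + dr < h - ha) and (hl <= c + dc < w - hl):
                    offsets[i] = (dr, dc)
                    break
    loss_mask = np.zeros(shape, dtype=bool)
    loss_mask[centers[:, 0], centers[:, 1]] = True
    return MaskPlan(shape, config.mask_shape, centers, offsets, loss_mask)


def apply_mask(patch: np.ndarray, plan: MaskPlan) -> np.ndarray:
    """Replace each masked strip with the strip at its offset.

    All reads come from the original input, so overlapping strips are resolved
    purely by plan order; pixels in no strip are returned bit-identical.
    """
    patch = np.asarray(patch)
    if patch.shape != plan.shape:
        raise ValueError(f"patch shape {patch.shape} does not match plan {plan.shape}")
    out = patch.copy()
    ha, hl = plan.mask_shape[0] // 2, plan.mask_shape[1] // 2
    for (r, c), (dr, dc) in zip(plan.centers, plan.offsets):
        out[r - ha:r + ha + 1, c - hl:c + hl + 1] = \
            patch[r + dr - ha:r + dr + ha + 1, c + dc - hl:c + dc + hl + 1]
    return out
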