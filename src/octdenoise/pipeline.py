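"""Streaming buffer inference pipeline and reference filters.

A reconstruction buffer (2D slab of consecutive A-scans, log-scaled, before
black-level subtraction) is split laterally into 4 sub-buffers that run as the
4 channels of the pseudo-batched network.  Each sub-buffer is padded by 20
A-scans per side: at the two outer edges by repeating the first/last A-scan,
at interior cuts by the true continuation, so recombination (dropping the
overlap) is seam-free whenever the padding covers the receptive half-width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve

from .network import UNet
from .phantom import ConfigurationError


@dataclass
class BufferSpec:
    """Geometry of the buffer split.

    The lateral size must divide evenly into ``sub_buffer_count`` cores and
    each core width must be divisible by 4, so the pooling grids of sub-buffer
    and whole-buffer inference coincide; ``pad`` must be even for the same
    reason and at least the model's receptive half-width.
    """

    sub_buffer_count: int = 4
    pad: int = 20
    black_level: float = 0.0

    def __post_init__(self) -> None:
        if self.sub_buffer_count < 1 or self.pad < 0:
            raise ConfigurationError("sub_buffer_count >= 1 and pad >= 0 required")
        if self.pad % 2:
            raise ConfigurationError("pad must be even (pooling-grid alignment)")

    def validate_width(self, width: int) -> int:
        k = self.sub_buffer_count
        if width % k:
            raise ConfigurationError(
                f"lateral size {width} not divisible by {k}; pre-pad explicitly")
        core = width // k
        if core % 4:
            raise ConfigurationError(
                f"core width {core} not divisible by 4 (two 2x poolings)")
        return core


def split_and_pad(buffer: np.ndarray, spec: BufferSpec) -> np.ndarray:
    """Split a buffer into a (k, H, W/k + 2*pad) stack of padded sub-buffers.

    Outer edges replicate the first/last A-scan; interior edges use the true
    continuation from the neighbouring core.
    """
    buffer = np.asarray(buffer)
    if buffer.ndim != 2:
        raise ConfigurationError("buffer must be 2D (axial x lateral)")
    h, w = buffer.shape
    core = spec.validate_width(w)
    p = spec.pad
    padded = np.pad(buffer, ((0, 0), (p, p)), mode="edge")
    out = np.empty((spec.sub_buffer_count, h, core + 2 * p), dtype=buffer.dtype)
    for i in range(spec.sub_buffer_count):
        out[i] = padded[:, i * core:i * core + core + 2 * p]
    return out


def recombine(channels: np.ndarray, spec: BufferSpec) -> np.ndarray:
    """Drop the pad overlap of each channel and re-concatenate the cores."""
    p = spec.pad
    cores = channels[:, :, p:channels.shape[2] - p] if p else channels
    return np.concatenate(list(cores), axis=1)


def denoise_buffer(buffer: np.ndarray, model4: UNet, spec: BufferSpec,
                   half: bool = False) -> np.ndarray:
    """Denoise one buffer through the split/pad/pseudo-batch/recombine path.

    ``model4`` must be a pseudo-batch export whose channel count equals
    ``spec.sub_buffer_count``.  The result has the input's shape and, given
    sufficient padding, equals whole-buffer inference of the underlying
    single-channel model away from the two outer pad margins.
    """
    buffer = np.asarray(buffer, dtype=np.float32)
    if model4.in_channels != spec.sub_buffer_count:
        raise ConfigurationError(
            f"model has {model4.in_channels} channels, spec expects "
            f"{spec.sub_buffer_count}")
    half_rf = model4.receptive_field()[1] // 2
    if spec.pad < half_rf:
        raise ConfigurationError(
            f"pad {spec.pad} below receptive half-width {half_rf}: "
            "recombination would leave silent seam artifacts")
    if buffer.shape[0] % 4:
        raise ConfigurationError("axial size must be divisible by 4")
    stack = split_and_pad(buffer, spec)
    pred = model4.forward_inference(stack[None], half=half)[0]
    return recombine(pred, spec)


def subtract_black_level(image: np.ndarray, level: float) -> np.ndarray:
    """Crop the noise floor: max(0, image - level)."""
    if level < 0:
        raise ValueError("black level must be >= 0")
    return np.maximum(np.asarray(image) - level, 0)


def gaussian_kernel2d(sigma: float) -> np.ndarray:
    """Isotropic Gaussian truncated at two standard deviations, sum 1.

    Side length is 2*ceil(2*sigma) + 1 (21 for sigma = 5).
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    radius = int(np.ceil(2 * sigma))
    x = np.arange(-radius, radius + 1)
    g1 = np.exp(-x * x / (2.0 * sigma * sigma))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_baseline(image: np.ndarray, sigma: float = 5.0) -> np.ndarray:
    """Reference denoiser: single 2D convolution with the truncated Gaussian,
    'same' size with edge replication."""
    kernel = gaussian_kernel2d(sigma)
    return convolve(np.asarray(image, dtype=np.float64), kernel, mode="nearest")
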