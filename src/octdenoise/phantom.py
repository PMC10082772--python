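"""Synthetic layered B-scan phantoms with controllable noise statistics.

The generator emulates log-scaled OCT B-scans of layered tissue (retina- or
cornea-like): a dark background above the tissue surface, a bright thin
membrane at the surface, and a stack of piecewise-constant reflectivity layers
separated by smooth wavy boundaries.  Speckle is multiplicative in intensity
but additive after logarithmic scaling, so noise is modelled as a zero-mean
additive Gaussian field in the log domain, with short-range axial correlation
(white noise smoothed by a separable Gaussian kernel and rescaled to the
target marginal sigma).  The clean signal, the noise field and their sum are
all returned, so v = s + n holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import convolve1d


class ConfigurationError(ValueError):
    """Inconsistent phantom or pipeline configuration."""


@dataclass
class BScanImage:
    """2D log-intensity image; axial dimension = rows, lateral = columns."""

    pixels: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("B-scan pixels must be 2D (axial x lateral)")
        if not np.isfinite(self.pixels).all():
            raise ValueError("B-scan contains non-finite values")

    @property
    def axial_size(self) -> int:
        return self.pixels.shape[0]

    @property
    def lateral_size(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic B-scan and its noise model.

    Correlation lengths are the sigmas (in pixels) of the Gaussian kernel that
    smooths the white-noise field; sigma_ax = 1.5 makes the axial correlation
    negligible beyond +-3 px, the regime a 7x1 axial mask is designed to hide,
    and sigma_lat = 0 leaves A-scans uncorrelated.
    """

    shape: tuple[int, int] = (128, 256)
    n_layers: int = 6
    reflectivities: tuple[float, ...] | None = None
    floor: float = 0.1
    wave_amplitude: float = 3.0
    wave_components: int = 3
    membrane: bool = True
    noise_sigma: float = 0.1
    sigma_ax: float = 1.5
    sigma_lat: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 0:
            raise ConfigurationError("n_layers must be >= 0")
        if not 0.0 <= self.floor <= 1.0:
            raise ConfigurationError("floor must be in [0, 1]")
        if self.noise_sigma < 0 or self.sigma_ax < 0 or self.sigma_lat < 0:
            raise ConfigurationError("sigmas must be >= 0")
        if self.reflectivities is not None:
            if len(self.reflectivities) != self.n_layers:
                raise ConfigurationError("need one reflectivity per layer")
            for r in self.reflectivities:
                if not self.floor <= r <= 1.0:
                    raise ConfigurationError("reflectivities must lie in [floor, 1]")


@dataclass
class ROISet:
    """14 foreground rectangles + 1 background rectangle (half-open, 0-based)."""

    foreground: list[tuple[int, int, int, int]]   # (row0, row1, col0, col1)
    background: tuple[int, int, int, int]

    def validate(self, shape: tuple[int, int], n_expected: int = 14) -> None:
        h, w = shape
        rects = list(self.foreground) + [self.background]
        if len(self.foreground) != n_expected:
            raise ConfigurationError(
                f"expected {n_expected} foreground ROIs, got {len(self.foreground)}")
        for r0, r1, c0, c1 in rects:
            if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
                raise ConfigurationError(f"ROI ({r0},{r1},{c0},{c1}) outside {shape}")
        b = self.background
        for f in self.foreground:
            if not (f[1] <= b[0] or b[1] <= f[0] or f[3] <= b[2] or b[3] <= f[2]):
                raise ConfigurationError("background ROI overlaps a foreground ROI")

    def save_csv(self, path) -> None:
        import pandas as pd
        rows = ([("fg", *r) for r in self.foreground]
                + [("bg", *self.background)])
        pd.DataFrame(rows, columns=["label", "row0", "row1", "col0", "col1"]
                     ).to_csv(path, index=False)

    @classmethod
    def load_csv(cls, path) -> "ROISet":
        import pandas as pd
        df = pd.read_csv(path)
        fg = [tuple(int(v) for v in row[["row0", "row1", "col0", "col1"]])
              for _, row in df[df.label == "fg"].iterrows()]
        bg_rows = df[df.label == "bg"]
        bg = tuple(int(v) for v in bg_rows.iloc[0][["row0", "row1", "col0", "col1"]])
        return cls(foreground=fg, background=bg)


@dataclass
class PhantomSample:
    """One noisy realization: noisy = clean + noise, exactly."""

    clean: BScanImage
    noise: np.ndarray
    noisy: BScanImage
    spec: PhantomSpec
    rois: ROISet | None = None


def layer_boundaries(spec: PhantomSpec) -> np.ndarray:
    """Boundary depths, shape (n_layers, lateral); strictly ordered per column.

    Boundary k separates layer k-1 from layer k (boundary 0 is the tissue
    surface).  Each boundary is a sum of seeded sinusoids around an evenly
    spaced base depth.
    """
    h, w = spec.shape
    if spec.n_layers == 0:
        return np.empty((0, w))
    rng = np.random.default_rng(spec.seed)
    base = np.linspace(0.20 * h, 0.85 * h, spec.n_layers)
    # cap total waviness so adjacent boundaries cannot meet on small images
    total = spec.wave_amplitude * (2.0 - 2.0 ** (1 - spec.wave_components))
    spacing = base[1] - base[0] if spec.n_layers > 1 else h
    amp_scale = min(1.0, 0.45 * spacing / total) if total > 0 else 1.0
    cols = np.arange(w)
    bounds = np.empty((spec.n_layers, w))
    for k in range(spec.n_layers):
        b = np.full(w, base[k])
        for j in range(spec.wave_components):
            amp = amp_scale * spec.wave_amplitude / (2.0 ** j)
            freq = rng.uniform(0.5, 3.0)
            phase = rng.uniform(0, 2 * np.pi)
            b = b + amp * np.sin(2 * np.pi * freq * cols / w + phase)
        bounds[k] = b
    if spec.n_layers > 1 and not (np.diff(bounds, axis=0) > 0).all():
        raise ConfigurationError(
            "layer boundaries cross; reduce wave_amplitude or n_layers")
    return bounds


def _default_reflectivities(spec: PhantomSpec) -> np.ndarray:
    if spec.reflectivities is not None:
        return np.asarray(spec.reflectivities, dtype=np.float64)
    rng = np.random.default_rng(spec.seed + 1)
    lo = min(spec.floor + 0.15, 1.0)
    return rng.uniform(lo, 0.9, size=spec.n_layers)


def make_clean_bscan(spec: PhantomSpec) -> BScanImage:
    """Render the piecewise-constant layered reflectivity image in [floor, 1]."""
    h, w = spec.shape
    if spec.n_layers == 0:
        return BScanImage(np.full((h, w), spec.floor))
    bounds = layer_boundaries(spec)
    refl = _default_reflectivities(spec)
    rows = np.arange(h)[:, None]
    # label = number of boundaries above the pixel; 0 => background
    label = (rows >= bounds[:, None, :]).sum(axis=0)
    values = np.concatenate([[spec.floor], refl])
    img = values[label]
    if spec.membrane:
        # bright 3-px membrane along the tissue surface (ILM-like)
        surface = bounds[0]
        dist = rows - surface[None, :]
        img[(dist >= 0) & (dist < 3)] = 1.0
    return BScanImage(img)


def _gauss_kernel(sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.ones(1)
    radius = int(np.ceil(6 * sigma))
    x = np.arange(-radius, radius + 1)
    g = np.exp(-x * x / (2.0 * sigma * sigma))
    return g / g.sum()


def correlated_noise(shape: tuple[int, int], sigma: float, sigma_ax: float,
                     sigma_lat: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian field with separable Gaussian autocorrelation.

    White noise is smoothed per axis (circular convolution keeps the field
    stationary), rescaled by the exact discrete-kernel factor to the target
    marginal sigma, and mean-centered.
    """
    if sigma == 0:
        return np.zeros(shape)
    field_ = rng.standard_normal(shape)
    norm = 1.0
    for axis, s in ((0, sigma_ax), (1, sigma_lat)):
        if s > 0:
            k = _gauss_kernel(s)
            field_ = convolve1d(field_, k, axis=axis, mode="wrap")
            norm *= np.sqrt((k * k).sum())
    field_ *= sigma / norm
    field_ -= field_.mean()
    return field_


def corrupt(clean: BScanImage, spec: PhantomSpec, seed: int) -> PhantomSample:
    """Add the log-domain speckle-like noise field to a clean B-scan."""
    rng = np.random.default_rng(seed)
    noise = correlated_noise(clean.pixels.shape, spec.noise_sigma,
                             spec.sigma_ax, spec.sigma_lat, rng)
    noisy = BScanImage(clean.pixels + noise, value_range=clean.value_range)
    return PhantomSample(clean=clean, noise=noise, noisy=noisy, spec=spec)


def place_rois(spec: PhantomSpec, n_foreground: int = 14,
               roi_size: tuple[int, int] | None = None) -> ROISet:
    """Programmatic 14+1 ROI placement: foreground inside layers, background
    above the tissue surface.  The rectangle size scales with the image so
    the set stays disjoint on small phantoms."""
    h, w = spec.shape
    rh, rw = roi_size if roi_size is not None else (
        max(2, min(6, h // 22)), max(6, min(14, w // 18)))
    if spec.n_layers == 0:
        raise ConfigurationError("cannot place foreground ROIs without layers")
    bounds = layer_boundaries(spec)
    top = int(np.floor(bounds[0].min()))
    if top - 2 < 3:
        raise ConfigurationError("no room for a background ROI above the surface")
    background = (1, top - 1, w // 4, w // 4 + max(rw, w // 2))
    margin = 4 if spec.membrane else 1
    fg: list[tuple[int, int, int, int]] = []
    n_cols = n_foreground
    col_starts = np.linspace(2, w - rw - 2, n_cols).astype(int)
    layer_cycle = 0
    for c0 in col_starts:
        placed = False
        for _ in range(spec.n_layers):
            k = layer_cycle % spec.n_layers
            layer_cycle += 1
            upper = bounds[k][c0:c0 + rw].max() + (margin if k == 0 else 1)
            lower = (bounds[k + 1][c0:c0 + rw].min() if k + 1 < spec.n_layers
                     else h - 2)
            if lower - upper >= rh + 1:
                r0 = int(np.ceil(upper + (lower - upper - rh) / 2))
                fg.append((r0, r0 + rh, int(c0), int(c0 + rw)))
                placed = True
                break
        if not placed:
            raise ConfigurationError(
                f"image too small to host {n_foreground}+1 disjoint ROIs")
    rois = ROISet(foreground=fg, background=background)
    rois.validate(spec.shape, n_expected=n_foreground)
    return rois


@dataclass
class EvalItem:
    """Held-out item: one noisy frame, the clean truth and an m-frame average."""

    sample: PhantomSample
    average: BScanImage
    m: int


@dataclass
class PhantomDataset:
    train: list[PhantomSample]
    val: list[PhantomSample]
    eval: list[EvalItem]
    spec: PhantomSpec
    seed: int


def make_dataset(n_train: int, n_val: int, n_eval: int, spec: PhantomSpec,
                 seed: int, m_avg: int = 100) -> PhantomDataset:
    """Generate disjoint-seeded train/val/eval phantoms.

    Each item gets its own clean geometry (distinct phantom seed) and noise
    seed; evaluation items additionally carry the mean of ``m_avg`` independent
    noisy realizations of the same clean image (the multi-frame-average
    reference, with no registration needed since phantoms are static) and a
    programmatic 14+1 ROI set.
    """
    if min(n_train, n_val, n_eval) < 0 or m_avg < 1:
        raise ConfigurationError("counts must be >= 0 and m_avg >= 1")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(3)

    def make_split(n_items: int, stream: np.random.SeedSequence, with_eval: bool):
        items = []
        child_seeds = stream.generate_state(2 * n_items + (n_items * m_avg if with_eval else 0),
                                            dtype=np.uint32)
        idx = 0
        for i in range(n_items):
            sp = replace(spec, seed=int(child_seeds[idx])); idx += 1
            clean = make_clean_bscan(sp)
            sample = corrupt(clean, sp, seed=int(child_seeds[idx])); idx += 1
            if not with_eval:
                items.append(sample)
                continue
            sample.rois = place_rois(sp)
            acc = sample.noisy.pixels.copy()
            for _ in range(m_avg - 1):
                acc += corrupt(clean, sp, seed=int(child_seeds[idx])).noisy.pixels
                idx += 1
            items.append(EvalItem(sample=sample,
                                  average=BScanImage(acc / m_avg), m=m_avg))
        return items

    return PhantomDataset(train=make_split(n_train, streams[0], False),
                          val=make_split(n_val, streams[1], False),
                          eval=make_split(n_eval, streams[2], True),
                          spec=spec, seed=seed)


def to_uint8(pixels: np.ndarray) -> np.ndarray:
    """8-bit export: clip to [0, 1], then round half away from zero."""
    clipped = np.clip(pixels, 0.0, 1.0) * 255.0
    return np.floor(clipped + 0.5).astype(np.uint8)
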