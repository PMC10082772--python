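"""Evaluation protocol: PSNR, SSIM, ROI-based CNR, noise autocorrelation and
mean +- 2*sample-SD aggregation.

PSNR uses the full intensity range R (255 on the 8-bit scale); CNR averages
(mu_f - mu_b) / sqrt(sigma_f^2 + sigma_b^2) over the foreground ROIs against
one shared background ROI, with population-convention (N denominator) ROI
statistics.  Aggregates over an image set report the mean and twice the
sample standard deviation (n-1 denominator), all images weighted equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .phantom import ROISet

SSIM_PARAMS = {"gaussian_weights": True, "sigma": 1.5, "K1": 0.01, "K2": 0.03}


def psnr(Y: np.ndarray, A: np.ndarray, R: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give +inf."""
    Y, A = np.asarray(Y, dtype=np.float64), np.asarray(A, dtype=np.float64)
    if Y.shape != A.shape:
        raise ValueError("shape mismatch")
    if R <= 0:
        raise ValueError("R must be > 0")
    mse = float(np.mean((Y - A) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(R * R / mse)


def ssim(Y: np.ndarray, A: np.ndarray, data_range: float = 255.0) -> float:
    """Mean structural similarity with an 11x11 Gaussian window (sigma 1.5)."""
    Y, A = np.asarray(Y, dtype=np.float64), np.asarray(A, dtype=np.float64)
    if Y.shape != A.shape:
        raise ValueError("shape mismatch")
    if min(Y.shape) < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(structural_similarity(A, Y, data_range=data_range, **SSIM_PARAMS))


def _roi_stats(img: np.ndarray, rect: tuple[int, int, int, int]) -> tuple[float, float]:
    r0, r1, c0, c1 = rect
    patch = img[r0:r1, c0:c1]
    if patch.size < 2:
        raise ValueError("ROI must contain at least 2 pixels")
    return float(patch.mean()), float(patch.var())  # population convention


def cnr(Y: np.ndarray, rois: ROISet) -> float:
    """Contrast-to-noise ratio averaged over the foreground ROIs."""
    Y = np.asarray(Y, dtype=np.float64)
    mu_b, var_b = _roi_stats(Y, rois.background)
    vals = []
    for rect in rois.foreground:
        mu_f, var_f = _roi_stats(Y, rect)
        denom = np.sqrt(var_f + var_b)
        if denom == 0.0:
            raise ValueError("zero variance in both ROIs of a pair")
        vals.append((mu_f - mu_b) / denom)
    return float(np.mean(vals))


def autocorr2d(field: np.ndarray, max_lag: int = 16) -> np.ndarray:
    """Normalized circular autocorrelation map, lag (0,0) at the center.

    Returns a (2*max_lag+1)^2 map with value 1 at the central (zero-lag)
    entry and symmetry under lag negation.
    """
    f = np.asarray(field, dtype=np.float64)
    if min(f.shape) < 2 * max_lag:
        raise ValueError("field too small for the requested max lag")
    f = f - f.mean()
    var = float(np.mean(f * f))
    if var == 0.0:
        raise ValueError("constant field has no autocorrelation")
    spec = np.fft.rfft2(f)
    corr = np.fft.irfft2(spec * np.conj(spec), s=f.shape) / (f.size * var)
    corr = np.fft.fftshift(corr)
    ch, cw = f.shape[0] // 2, f.shape[1] // 2
    return corr[ch - max_lag:ch + max_lag + 1, cw - max_lag:cw + max_lag + 1]


def axial_profile_mse(Y: np.ndarray, A: np.ndarray, col: int,
                      rows: slice | None = None) -> float:
    """MSE between single-column (A-scan) intensity profiles."""
    rows = rows if rows is not None else slice(None)
    d = np.asarray(Y, dtype=np.float64)[rows, col] - np.asarray(A, dtype=np.float64)[rows, col]
    return float(np.mean(d * d))


@dataclass
class MetricReport:
    """Per-image metrics plus mean and 2x sample-SD aggregates."""

    per_image: pd.DataFrame
    aggregate: pd.DataFrame
    crop: tuple[int, int, int, int] | None
    conventions: dict

    def save_csv(self, path) -> None:
        rows = self.per_image.copy()
        agg = self.aggregate.copy()
        agg.insert(0, "image", ["mean", "2sd"])
        pd.concat([rows, agg], ignore_index=True).to_csv(path, index=False)


def _aggregate(values: pd.Series) -> tuple[float, float]:
    vals = values[np.isfinite(values)]
    if len(vals) < len(values):
        warnings.warn("infinite per-image metric excluded from aggregation")
    if len(vals) == 0:
        return float("nan"), float("nan")
    if len(vals) == 1:
        warnings.warn("single image: 2-sigma dispersion reported as 0")
        return float(vals.iloc[0]), 0.0
    return float(vals.mean()), float(2.0 * vals.std(ddof=1))


def evaluate(denoised: list[np.ndarray], reference: list[np.ndarray],
             rois: list[ROISet] | None = None,
             crop: tuple[int, int, int, int] | None = None,
             data_range: float = 255.0) -> MetricReport:
    """Score an image set: PSNR/SSIM on the crop, CNR on the full ROI sets.

    ``crop`` is (row0, row1, col0, col1), half-open; images are assumed to be
    on the same scale as ``data_range``.
    """
    if len(denoised) == 0:
        raise ValueError("empty evaluation set")
    if len(denoised) != len(reference):
        raise ValueError("denoised/reference counts differ")
    rows = []
    for i, (y, a) in enumerate(zip(denoised, reference)):
        yc, ac = (y, a) if crop is None else (
            y[crop[0]:crop[1], crop[2]:crop[3]], a[crop[0]:crop[1], crop[2]:crop[3]])
        row = {"image": i,
               "psnr": psnr(yc, ac, R=data_range),
               "ssim": ssim(yc, ac, data_range=data_range)}
        if rois is not None:
            row["cnr"] = cnr(y, rois[i])
        rows.append(row)
    per_image = pd.DataFrame(rows)
    agg = {}
    for col in per_image.columns[1:]:
        mu, two_sd = _aggregate(per_image[col])
        agg[col] = [mu, two_sd]
    return MetricReport(per_image=per_image, aggregate=pd.DataFrame(agg),
                        crop=crop,
                        conventions={"roi_variance": "population (N)",
                                     "aggregate_sd": "sample (n-1), doubled",
                                     "data_range": data_range,
                                     **SSIM_PARAMS})
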