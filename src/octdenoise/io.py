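"""Disk formats: 8-bit TIFF/PNG B-scans, plain-text manifests, ROI CSVs.

A dataset directory holds one image file per B-scan plus ``manifest.txt``
(flat ``key = value`` lines recording the generator spec and seeds) and one
ROI CSV per evaluation image.
"""

from __future__ import annotations

import ast
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .phantom import BScanImage, PhantomDataset, PhantomSpec, to_uint8


def save_image(path, pixels: np.ndarray) -> None:
    """Write a [0,1]-ranged float image as 8-bit TIFF or PNG."""
    path = Path(path)
    data = to_uint8(pixels)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def load_image(path) -> np.ndarray:
    """Read an 8-bit grayscale image back to float in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    return np.asarray(data, dtype=np.float64) / 255.0


def write_manifest(path, entries: dict) -> None:
    with open(path, "w") as fh:
        for key, val in entries.items():
            fh.write(f"{key} = {val!r}\n")


def read_manifest(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(" = ")
            out[key] = ast.literal_eval(val)
    return out


def save_dataset(directory, dataset: PhantomDataset, fmt: str = "tiff") -> None:
    """Write a phantom dataset: images per split, ROI CSVs, manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = {"tiff": "tif", "png": "png"}[fmt]
    spec = dataset.spec
    for split, items in (("train", dataset.train), ("val", dataset.val)):
        for i, sample in enumerate(items):
            save_image(directory / f"{split}_{i:03d}_noisy.{ext}",
                       sample.noisy.pixels)
    for i, item in enumerate(dataset.eval):
        save_image(directory / f"eval_{i:03d}_noisy.{ext}", item.sample.noisy.pixels)
        save_image(directory / f"eval_{i:03d}_clean.{ext}", item.sample.clean.pixels)
        save_image(directory / f"eval_{i:03d}_avg.{ext}", item.average.pixels)
        item.sample.rois.save_csv(directory / f"eval_{i:03d}_rois.csv")
    write_manifest(directory / "manifest.txt", {
        "seed": dataset.seed,
        "n_train": len(dataset.train), "n_val": len(dataset.val),
        "n_eval": len(dataset.eval),
        "m_avg": dataset.eval[0].m if dataset.eval else 1,
        "format": fmt,
        **{f"spec.{k}": v for k, v in spec.__dict__.items()},
    })


def load_split(directory, split: str) -> list[np.ndarray]:
    directory = Path(directory)
    files = sorted(directory.glob(f"{split}_*_noisy.*"))
    if not files:
        raise FileNotFoundError(f"no {split} images under {directory}")
    return [load_image(f) for f in files]


def manifest_spec(manifest: dict) -> PhantomSpec:
    kw = {k[5:]: v for k, v in manifest.items() if k.startswith("spec.")}
    if "shape" in kw:
        kw["shape"] = tuple(kw["shape"])
    if kw.get("reflectivities") is not None:
        kw["reflectivities"] = tuple(kw["reflectivities"])
    return PhantomSpec(**kw)
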