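"""Image and dataset I/O: 8-bit grayscale PNG, single-slice NIfTI, and the
sidecar labels CSV (columns ``id,label,file``; UTF-8, LF endings).

PNG quantization is fixed-point: intensities are scaled by 255 and rounded
half-up, and reads divide by 255, so a write/read/write round trip is
byte-identical.  External images of unknown dynamic range (NIfTI, or PNG
with ``normalize="minmax"``) are instead rescaled to [0, 1] per image.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from PIL import Image

from .phantom import ImageSample

__all__ = ["save_png", "load_png", "save_nifti", "load_nifti",
           "write_dataset", "read_dataset"]


def quantize(pixels: np.ndarray) -> np.ndarray:
    """Scale [0,1] intensities to 8-bit, rounding half-up."""
    return np.floor(np.clip(pixels, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def save_png(sample: ImageSample, path) -> None:
    Image.fromarray(quantize(sample.pixels), mode="L").save(path, format="PNG")


def load_png(path, label: int = 0, sample_id: str | None = None,
             normalize: str = "fixed") -> ImageSample:
    """Read an 8-bit grayscale PNG.

    ``normalize="fixed"`` divides by 255 (exact inverse of :func:`quantize`,
    so write/read/write is byte-identical); ``"minmax"`` rescales per image,
    for external images of unknown dynamic range.
    """
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    pixels = arr / 255.0 if normalize == "fixed" else _rescale(arr)
    return ImageSample(pixels=pixels, label=label,
                       id=sample_id or Path(path).stem).validate()


def save_nifti(sample: ImageSample, path) -> None:
    vol = sample.pixels.astype(np.float32)[:, :, None]  # single-slice volume
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def load_nifti(path, label: int = 0, sample_id: str | None = None) -> ImageSample:
    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if vol.ndim == 3:
        vol = vol[:, :, 0]
    return ImageSample(pixels=_rescale(vol), label=label,
                       id=sample_id or Path(path).stem).validate()


def _rescale(arr: np.ndarray) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def write_dataset(samples: Sequence[ImageSample], directory,
                  fmt: str = "png") -> Path:
    """Write images plus a ``labels.csv`` sidecar; returns the CSV path."""
    if fmt not in ("png", "nifti"):
        raise ValueError(f"format must be 'png' or 'nifti', got {fmt!r}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / "labels.csv"
    ext = "png" if fmt == "png" else "nii.gz"
    with open(csv_path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "label", "file"])
        for s in samples:
            fname = f"{s.id.replace('/', '_')}.{ext}"
            (save_png if fmt == "png" else save_nifti)(s, directory / fname)
            writer.writerow([s.id, s.label, fname])
    return csv_path


def read_dataset(directory) -> list[ImageSample]:
    """Read a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    csv_path = directory / "labels.csv"
    if not csv_path.exists():
        raise FileNotFoundError(f"no labels.csv in {directory}")
    samples = []
    with open(csv_path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            path = directory / row["file"]
            loader = load_nifti if path.suffix in (".gz", ".nii") else load_png
            samples.append(loader(path, label=int(row["label"]), sample_id=row["id"]))
    return samples
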