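"""Readers and writers: NIfTI volumes, PNG slice pairs, benchmark manifests.

2-D phantoms are written as 16-bit PNG intensity images (with the affine
rescale recorded in the manifest so loading restores float values to
quantisation precision) plus 8-bit mask PNGs.  3-D volumes go through
NIfTI with spacing preserved in the header.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import case_normalise
from .trainer import DataStream

__all__ = ["read_volume", "write_volume", "write_png_image", "read_png_image",
           "save_benchmark", "load_benchmark"]

_U16 = 65535


def read_volume(path, normalise: bool = False) -> tuple[np.ndarray, tuple]:
    """Load a NIfTI (.nii/.nii.gz) or PNG image as (array, spacing).

    NIfTI arrays keep their on-disk axis order and voxel spacing; PNGs get
    unit spacing.  ``normalise`` applies case-wise zero-mean/unit-variance
    scaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            img = nib.load(str(path))
            data = np.asarray(img.dataobj, dtype=float)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:data.ndim])
        elif name.endswith(".png"):
            data, spacing = read_png_image(path)
        else:
            raise ValueError(f"unsupported image format: {path}")
    except (nib.filebasedimages.ImageFileError, OSError) as err:
        raise ValueError(f"unreadable image {path}: {err}") from err
    if normalise:
        data = case_normalise(data)
    return data, spacing


def write_volume(path, array: np.ndarray, spacing=None) -> None:
    """Write a float array as NIfTI with the given voxel spacing."""
    array = np.asarray(array, dtype=np.float64)
    affine = np.eye(4)
    if spacing is not None:
        for i, z in enumerate(spacing[:3]):
            affine[i, i] = float(z)
    img = nib.Nifti1Image(array, affine)
    if spacing is not None:
        img.header.set_zooms(tuple(float(z) for z in spacing[:array.ndim]))
    nib.save(img, str(path))


def write_png_image(path, array: np.ndarray) -> tuple[float, float]:
    """Quantise a float 2-D array to 16-bit PNG; returns (vmin, vmax)."""
    array = np.asarray(array, dtype=float)
    if array.ndim != 2:
        raise ValueError(f"PNG export needs a 2-D array, got shape {array.shape}")
    vmin, vmax = float(array.min()), float(array.max())
    scale = (vmax - vmin) or 1.0
    q = np.round((array - vmin) / scale * _U16).astype(np.uint16)
    iio.imwrite(Path(path), q)
    return vmin, vmax


def read_png_image(path, vmin: float = 0.0, vmax: float = 1.0
                   ) -> tuple[np.ndarray, tuple]:
    """Read a PNG back to float, undoing the 16-bit quantisation."""
    raw = np.asarray(iio.imread(Path(path)), dtype=float)
    if raw.ndim == 3:  # collapse any colour axis
        raw = raw.mean(axis=-1)
    data = raw / _U16 * (vmax - vmin) + vmin
    return data, (1.0, 1.0)


def save_benchmark(stream: DataStream, outdir) -> Path:
    """Write a 2-D benchmark as PNG pairs plus a ``manifest.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    parts = [("labelled", stream.labelled), ("unlabelled", stream.unlabelled),
             ("val", stream.val), ("test", stream.test)]
    for split, items in parts:
        for i, item in enumerate(items):
            image, mask = item if isinstance(item, tuple) else (item, None)
            img2d = np.asarray(image)[0] if np.asarray(image).ndim == 3 else np.asarray(image)
            img_path = outdir / f"{split}_{i:04d}.png"
            vmin, vmax = write_png_image(img_path, img2d)
            row = {"path": img_path.name, "split": split, "index": i,
                   "vmin": vmin, "vmax": vmax, "mask_path": "",
                   "foreground": -1,
                   "n_channels": int(np.asarray(image).shape[0])
                   if np.asarray(image).ndim == 3 else 1}
            if mask is not None:
                mask_path = outdir / f"{split}_{i:04d}_mask.png"
                iio.imwrite(mask_path, (np.asarray(mask, bool) * 255).astype(np.uint8))
                row["mask_path"] = mask_path.name
                row["foreground"] = int(np.count_nonzero(mask))
            rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_benchmark(outdir) -> DataStream:
    """Inverse of :func:`save_benchmark`."""
    outdir = Path(outdir)
    manifest = outdir / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {outdir}")
    table = pd.read_csv(manifest, keep_default_na=False)
    stream = DataStream()
    for _, row in table.iterrows():
        data, _ = read_png_image(outdir / row["path"], row["vmin"], row["vmax"])
        image = np.broadcast_to(data, (int(row["n_channels"]),) + data.shape).copy()
        if row["mask_path"]:
            mask = np.asarray(iio.imread(outdir / row["mask_path"])) > 127
            pair = (image, mask)
        else:
            pair = None
        if row["split"] == "unlabelled":
            stream.unlabelled.append(image)
        else:
            getattr(stream, row["split"]).append(pair)
    return stream
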