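"""Sequence readers and result writers.

Sequences are read from a directory of numbered single-channel PNG/TIFF
files, from one multi-page TIFF (2D frames), or — for 3D data — from a
directory of per-frame TIFF stacks.  Stored integer values are
preserved exactly (no rescaling).  Results are written as binary mask
PNGs, contour polylines and a diagnostics table as CSV, plus the
effective configuration as YAML.
"""

from __future__ import annotations

import csv
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .config import RunConfig

__all__ = ["read_sequence", "write_outputs", "read_mask", "extract_contours"]

_EXTS = (".png", ".tif", ".tiff")


def read_sequence(path) -> list:
    """Frames, lexicographic order, as float arrays with exact values."""
    path = Path(path)
    if path.is_file():
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("single-file input must be a multi-page TIFF")
        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        return [np.asarray(f, dtype=float) for f in data]
    if not path.is_dir():
        raise FileNotFoundError(path)
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in _EXTS)
    if not files:
        raise ValueError(f"no PNG/TIFF files in {path}")
    frames = []
    for p in files:
        if p.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(p))
        else:
            arr = iio.imread(p)
        if arr.ndim == 3 and arr.shape[-1] in (3, 4) \
                and p.suffix.lower() == ".png":
            raise ValueError(f"{p} is not single-channel")
        frames.append(np.asarray(arr, dtype=float))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
    return frames


def read_mask(path) -> np.ndarray:
    """Binary mask from a raster file (any nonzero value is foreground)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(path)
    return np.asarray(arr) > 0


def extract_contours(mask: np.ndarray) -> list:
    """Closed sub-pixel polylines of a 2D mask (pixel-center coordinates).

    Returns a list of (n, 2) arrays, one per connected boundary
    component, using the 0.5 iso-level of the binary image.
    """
    from skimage import measure
    return measure.find_contours(np.asarray(mask, dtype=float), 0.5)


def write_outputs(masks, contours, diagnostics, out_dir,
                  config: RunConfig = None) -> dict:
    """Write per-frame mask PNGs, contour and diagnostics CSVs.

    ``contours`` may be ``None`` (recomputed for 2D masks, skipped for
    3D).  Returns the paths written.  Contour coordinates are 0-based
    pixel-center values: column ``x`` is the first array axis, ``y`` the
    second.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {"masks": []}
    for k, mask in enumerate(masks):
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            p = out_dir / f"mask_{k:04d}.png"
            iio.imwrite(p, (mask.astype(np.uint8) * 255))
        else:
            p = out_dir / f"mask_{k:04d}.tif"
            tifffile.imwrite(str(p), mask.astype(np.uint8) * 255)
        paths["masks"].append(p)

    if contours is None and np.asarray(masks[0]).ndim == 2:
        contours = [extract_contours(m) for m in masks]
    if contours is not None:
        cpath = out_dir / "contours.csv"
        with open(cpath, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["frame", "component", "x", "y"])
            for k, comps in enumerate(contours):
                for ci, poly in enumerate(comps):
                    for pt in poly:
                        wr.writerow([k, ci] + [f"{v:.4f}" for v in pt])
        paths["contours"] = cpath

    dpath = out_dir / "diagnostics.csv"
    keys = sorted({k for row in diagnostics for k in row})
    keys = ["frame"] + [k for k in keys if k != "frame"]
    with open(dpath, "w", newline="") as fh:
        wr = csv.DictWriter(fh, fieldnames=keys)
        wr.writeheader()
        for row in diagnostics:
            wr.writerow(row)
    paths["diagnostics"] = dpath

    if config is not None:
        cfgpath = out_dir / "config.yaml"
        config.to_yaml(cfgpath)
        paths["config"] = cfgpath
    return paths
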