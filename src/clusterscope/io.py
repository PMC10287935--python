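"""File I/O: TIFF stacks and movies, label masks, tables, configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF z-stack as a (z, y, x) float array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr, dtype=float)


def write_stack(path, stack: np.ndarray) -> None:
    """Write a (z, y, x) stack as one TIFF page per plane."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_movie(path) -> np.ndarray:
    """Read a TIFF movie as (t, z, y, x); 3D files are taken as (t, y, x)."""
    arr = tifffile.imread(str(path))
    return np.asarray(arr, dtype=float)


def write_movie(path, movie: np.ndarray) -> None:
    """Write a (t, z, y, x) movie as an ImageJ-compatible TZYX TIFF."""
    arr = np.asarray(movie, dtype=np.float32)
    tifffile.imwrite(str(path), arr, imagej=True,
                     metadata={"axes": "TZYX" if arr.ndim == 4 else "TYX"})


def write_label_mask(path, labels: np.ndarray) -> None:
    """Write a label image as a 16-bit TIFF."""
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.uint16))


def read_label_mask(path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def load_yaml(path):
    return yaml.safe_load(Path(path).read_text())


def dump_yaml(path, obj) -> None:
    Path(path).write_text(yaml.safe_dump(obj))
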