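"""File formats: float TIFF frames, HDF5 stacks, 8-bit mask images."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import GapMask

__all__ = [
    "save_frame",
    "load_frame",
    "save_stack_hdf5",
    "load_stack_hdf5",
    "save_mask",
    "load_mask",
]


def save_frame(path: str | Path, frame: np.ndarray) -> None:
    """Write one frame as 32-bit float TIFF."""
    tifffile.imwrite(str(path), np.asarray(frame, dtype=np.float32))


def load_frame(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.float64)


def save_stack_hdf5(
    path: str | Path, datasets: dict[str, np.ndarray], attrs: dict | None = None
) -> None:
    """Write named float32 datasets (plus optional root attributes)."""
    with h5py.File(str(path), "w") as f:
        for name, arr in datasets.items():
            f.create_dataset(name, data=np.asarray(arr, dtype=np.float32))
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def load_stack_hdf5(path: str | Path, names: list[str] | None = None) -> dict[str, np.ndarray]:
    with h5py.File(str(path), "r") as f:
        names = names or list(f.keys())
        return {name: np.asarray(f[name], dtype=np.float64) for name in names}


def save_mask(path: str | Path, mask: GapMask) -> None:
    """Write a mask as single-channel 8-bit image (0 = valid, 255 = gap)."""
    tifffile.imwrite(str(path), np.where(mask.raster, 255, 0).astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit mask image back to a boolean raster (nonzero = gap)."""
    return np.asarray(tifffile.imread(str(path))) != 0
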