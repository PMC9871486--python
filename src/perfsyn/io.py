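"""Volume I/O and seeding infrastructure.

Internal canonical axis order is (slice, height, width[, time]).  NIfTI
stores (x, y, z[, t]); on write the slice axis is moved to the third on-disk
position and the permutation reversed on read, so a write/read round trip is
bitwise exact.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import nibabel as nib
import numpy as np


def write_volume(path: str | Path, array: np.ndarray, affine: np.ndarray | None = None) -> Path:
    path = Path(path)
    arr = np.asarray(array)
    if arr.ndim not in (3, 4):
        raise ValueError(f"expected a 3D or 4D array, got ndim={arr.ndim}")
    disk = np.moveaxis(arr, 0, 2)  # (h, w, slice[, t])
    img = nib.Nifti1Image(disk, affine if affine is not None else np.eye(4))
    nib.save(img, str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Return (array in canonical order, affine, header metadata)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        disk = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises several types for malformed input
        raise IOError(f"cannot read {path} as NIfTI: {exc}") from exc
    if disk.ndim not in (3, 4):
        raise IOError(f"{path}: expected 3D or 4D NIfTI, got ndim={disk.ndim}")
    arr = np.moveaxis(disk, 2, 0)
    meta = {"zooms": tuple(float(z) for z in img.header.get_zooms())}
    return np.ascontiguousarray(arr), img.affine, meta


def substream(root_seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream so each stage draws independent randomness
    from one root seed and can be re-run in isolation."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, tag]))


def substream_seed(root_seed: int, name: str) -> int:
    """A plain integer seed (< 2^31) derived for stage ``name``."""
    tag = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return int(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, tag]).generate_state(1)[0] & 0x7FFFFFFF)
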