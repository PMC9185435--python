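"""Grayscale image I/O and the 8-fold dihedral test-time averaging path.

Images are PNG or TIFF, converted on read to float64 in [0,1] (integer
files are scaled by their bit depth; multi-channel inputs are reduced by
the channel mean).  Writing inverts the scaling; 8-bit round trips are
accurate to half a quantization step (1/510) and float TIFF round trips
are bit-exact.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .trainer import dihedral, dihedral_inverse

__all__ = ["read_gray", "write_gray", "denoise_tta"]


def read_gray(path) -> np.ndarray:
    """Read a PNG/TIFF as a 2-D float64 array in [0,1] (nominally)."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        scale = 1.0
    arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"unsupported image layout {arr.shape} in {path}")
    return arr / scale


def write_gray(img: np.ndarray, path, bitdepth: int | str = 8) -> None:
    """Write a [0,1] image; `bitdepth` 8 or 16 (PNG/TIFF integer, clipped)
    or 'float' (32-bit float TIFF, values untouched)."""
    img = np.asarray(img, dtype=np.float64)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if bitdepth == "float":
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("float output requires a .tif/.tiff path")
        tifffile.imwrite(path, img.astype(np.float32))
        return
    if bitdepth == 8:
        q = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    elif bitdepth == 16:
        q = np.clip(np.round(img * 65535.0), 0, 65535).astype(np.uint16)
    else:
        raise ValueError("bitdepth must be 8, 16 or 'float'")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, q)
    else:
        iio.imwrite(path, q)


def denoise_tta(net, img: np.ndarray, single_pass: bool = False) -> np.ndarray:
    """Denoise with 8-fold dihedral test-time averaging.

    The image is rotated/mirrored into all 8 symmetries of the square,
    denoised, inverse-transformed, and the outputs are averaged pixelwise
    — enforcing the rotational symmetry the denoiser should have.  Each
    transformed pass is J-invariant and averaging preserves that, so the
    TTA output is itself J-invariant.  No clipping happens here; clip at
    export/metric time.
    """
    img = np.asarray(img, dtype=np.float64)
    if single_pass:
        return net.apply(img)
    acc = np.zeros_like(img)
    for k in range(8):
        out = net.apply(np.ascontiguousarray(dihedral(img, k)))
        acc += dihedral_inverse(out, k)
    return acc / 8.0
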