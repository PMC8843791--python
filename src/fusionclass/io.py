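"""Image loading and saving.

All images enter the pipeline as float64 arrays in [0, 1] ("GrayImage"
contract).  8-bit inputs are divided by 255, 16-bit by 65535.  RGB inputs
can be collapsed to luminance with :func:`fusionclass.preprocess.to_grayscale`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import imageio.v3 as iio


def load_image(path: str | Path, *, grayscale: bool = True) -> np.ndarray:
    """Read a PNG/TIFF (or DICOM) image as a float64 array in [0, 1].

    Parameters
    ----------
    path
        Image file.  ``.dcm`` files are read with pydicom and rescaled by
        their stored bit depth; everything else goes through imageio.
    grayscale
        Collapse a 3-channel image to luminance.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        import pydicom

        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(np.float64)
        rng = float(arr.max()) or 1.0
        img = arr / rng
    else:
        arr = iio.imread(path)
        img = _rescale(arr)
    if grayscale and img.ndim == 3:
        from .preprocess import to_grayscale

        img = to_grayscale(img[..., :3])
    return img


def _rescale(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:  # unknown integer scale; normalize defensively
        arr = arr / arr.max()
    return np.clip(arr, 0.0, 1.0)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0, 1] image as 8-bit PNG (or TIFF by extension)."""
    out = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (out * 255.0 + 0.5).astype(np.uint8))


def save_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as a 0/255 PNG."""
    iio.imwrite(Path(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
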