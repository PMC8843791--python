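"""2-D DCT, inverse DCT, and coefficient-domain image fusion.

The forward transform is the orthonormal type-II DCT (separable cosine
kernels); its inverse is the orthonormal type-III DCT.  With this scaling
the round trip is exact to floating point and Parseval's identity holds,
so the *average* fusion rule in the coefficient domain is exactly pixelwise
averaging — the frequency-domain formulation matters for rules that are
nonlinear in the coefficients (e.g. ``max_magnitude``).
"""

from __future__ import annotations

import numpy as np
import scipy.fft

FUSION_RULES = ("average", "max_magnitude")


def dct2(img: np.ndarray, block: int | None = None) -> np.ndarray:
    """Orthonormal 2-D type-II DCT (whole-image, or per 8x8-style blocks).

    For a constant image of value ``c`` and size M x N the only nonzero
    coefficient is the DC term ``c * sqrt(M * N)``.
    """
    img = np.asarray(img, dtype=np.float64)
    if block is None:
        return scipy.fft.dctn(img, type=2, norm="ortho")
    return _blockwise(img, block, lambda b: scipy.fft.dctn(b, type=2, norm="ortho"))


def idct2(coeffs: np.ndarray, block: int | None = None) -> np.ndarray:
    """Inverse of :func:`dct2` (orthonormal type-III DCT).  Not clipped."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if block is None:
        return scipy.fft.idctn(coeffs, type=2, norm="ortho")
    return _blockwise(coeffs, block,
                      lambda b: scipy.fft.idctn(b, type=2, norm="ortho"))


def _blockwise(arr: np.ndarray, block: int, fn) -> np.ndarray:
    # edge blocks are transformed at their natural (smaller) size, so the
    # block decomposition is exactly invertible for any image shape
    if block < 1:
        raise ValueError("block size must be >= 1")
    out = np.empty_like(arr)
    for i in range(0, arr.shape[0], block):
        for j in range(0, arr.shape[1], block):
            out[i:i + block, j:j + block] = fn(arr[i:i + block, j:j + block])
    return out


def fuse_images(a: np.ndarray, b: np.ndarray, rule: str = "average",
                block: int | None = None) -> np.ndarray:
    """Fuse two registered images in the DCT domain; output clipped to [0, 1].

    ``average`` takes the elementwise mean of the two coefficient grids
    (the default rule); ``max_magnitude`` keeps, per frequency, the
    coefficient of larger absolute value (exact ties resolved toward the
    first input).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(
            "images differ in shape; register/resample them to a common grid first"
        )
    if rule not in FUSION_RULES:
        raise ValueError(f"unknown fusion rule {rule!r}; choose from {FUSION_RULES}")
    ca = dct2(a, block=block)
    cb = dct2(b, block=block)
    if rule == "average":
        fused = (ca + cb) / 2.0
    else:
        fused = np.where(np.abs(ca) >= np.abs(cb), ca, cb)
    return np.clip(idct2(fused, block=block), 0.0, 1.0)
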