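"""Preprocessing: grayscale conversion, CLAHE, rigid registration.

Enhancement precedes fusion: both channels are CLAHE-equalized, the
functional (target) image is rigidly registered onto the anatomical
(reference) grid by maximizing normalized cross-correlation, and only then
are the images fused.  Everything here is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, transform as sktransform

#: ITU-R BT.601 luminance weights.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def to_grayscale(rgb: np.ndarray) -> np.ndarray:
    """Collapse a 3-channel [0,1] image to luminance; gray passes through."""
    img = np.asarray(rgb, dtype=np.float64)
    if img.ndim == 2:
        return img
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("expected a 2-D gray image or an (M, N, 3) RGB image")
    w = np.asarray(LUMA_WEIGHTS)
    return np.clip(img @ w, 0.0, 1.0)


def clahe(img: np.ndarray, tile_grid: tuple[int, int] = (8, 8),
          clip_limit: float = 0.01, nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Per-tile histogram equalization with the histogram clipped at
    ``clip_limit`` (excess mass redistributed) and bilinear blending between
    tile mappings.  ``tile_grid`` is the number of tiles along (rows, cols).
    A constant image is returned unchanged (degenerate histogram).
    """
    img = np.asarray(img, dtype=np.float64)
    if not (0.0 < clip_limit <= 1.0):
        raise ValueError("clip_limit must be in (0, 1]")
    rows, cols = img.shape
    if tile_grid[0] > rows or tile_grid[1] > cols:
        raise ValueError("tile_grid larger than image dimensions")
    if np.ptp(img) < 1e-12:
        return img.copy()
    kernel = (max(1, rows // tile_grid[0]), max(1, cols // tile_grid[1]))
    out = exposure.equalize_adapthist(
        np.clip(img, 0.0, 1.0), kernel_size=kernel,
        clip_limit=clip_limit, nbins=nbins,
    )
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid + isotropic-scale transform: x-shift, y-shift, CCW rotation, scale."""

    dx: float = 0.0
    dy: float = 0.0
    theta: float = 0.0  # degrees
    scale: float = 1.0

    def __post_init__(self):
        if not (0.5 <= self.scale <= 2.0):
            raise ValueError("scale out of the [0.5, 2.0] search bounds")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    registered: np.ndarray
    similarity: float


def apply_rigid(img: np.ndarray, dx: float = 0.0, dy: float = 0.0,
                theta: float = 0.0, scale: float = 1.0,
                cval: float = 0.0) -> np.ndarray:
    """Rotate/scale about the image center, then translate by (dx, dy).

    ``dx`` moves content along columns (x), ``dy`` along rows (y); ``theta``
    is a counterclockwise rotation in degrees.  Bilinear interpolation,
    out-of-frame pixels filled with ``cval``.
    """
    img = np.asarray(img, dtype=np.float64)
    if dx == 0.0 and dy == 0.0 and theta == 0.0 and scale == 1.0:
        return img.copy()
    rows, cols = img.shape
    c = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    t = np.array([dy, dx])
    rad = math.radians(theta)
    # forward: out = s * R @ (in - c) + c + t  (row/col coords, CCW in x-right
    # y-down display convention) -> inverse map for ndimage
    rot = np.array([[math.cos(rad), math.sin(rad)],
                    [-math.sin(rad), math.cos(rad)]])
    inv = rot.T / scale
    offset = c - inv @ (c + t)
    return ndimage.affine_transform(img, inv, offset=offset, order=1,
                                    mode="constant", cval=cval)


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return -1.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _grid(center: float, half: float, step: float) -> np.ndarray:
    n = int(round(half / step))
    return center + step * np.arange(-n, n + 1)


def register(target: np.ndarray, reference: np.ndarray) -> RegistrationResult:
    """Rigid intensity-based registration by coarse-to-fine NCC grid search.

    Finds the transform of ``target`` that maximizes the normalized
    cross-correlation with ``reference``.  Search space: translations
    within +/-16 px, rotation within +/-15 degrees, isotropic scale within
    [0.9, 1.1]; a 3-level image pyramid keeps the exhaustive search cheap
    and the final level resolves 1 px / 0.5 degrees.  The identity transform
    is always evaluated, so the returned similarity can never fall below
    the unregistered one.  Fully deterministic.
    """
    target = np.asarray(target, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if target.shape != reference.shape:
        target = sktransform.resize(target, reference.shape, order=1,
                                    anti_aliasing=True)
    if target.std() == 0 or reference.std() == 0:
        raise ValueError("registration undefined for a flat image")

    cval = float(np.median(target))
    best = (0.0, 0.0, 0.0, 1.0)

    levels = [
        # (downsample factor, (dx half-range, step), (theta half, step),
        #  scale candidates around current best)
        (4, (16.0, 4.0), (15.0, 3.0), np.array([0.9, 0.95, 1.0, 1.05, 1.1])),
        (2, (4.0, 2.0), (3.0, 1.0), None),
        (1, (2.0, 1.0), (1.0, 0.5), None),
    ]
    for factor, (dhalf, dstep), (thalf, tstep), scales in levels:
        if factor > 1:
            ref_s = sktransform.rescale(reference, 1.0 / factor, order=1,
                                        anti_aliasing=True)
            tgt_s = sktransform.rescale(target, 1.0 / factor, order=1,
                                        anti_aliasing=True)
        else:
            ref_s, tgt_s = reference, target
        if scales is None:
            scales = np.clip(best[3] + np.array([-0.025, 0.0, 0.025]),
                             0.5, 2.0)
        dxs = _grid(best[0], dhalf, dstep)
        dys = _grid(best[1], dhalf, dstep)
        thetas = _grid(best[2], thalf, tstep)
        score_best = -2.0
        for s in scales:
            for th in thetas:
                for dy in dys:
                    for dx in dxs:
                        warped = apply_rigid(tgt_s, dx / factor, dy / factor,
                                             th, s, cval=cval)
                        sc = _ncc(ref_s, warped)
                        if sc > score_best:
                            score_best = sc
                            best = (float(dx), float(dy), float(th), float(s))

    identity_sim = _ncc(reference, target)
    registered = apply_rigid(target, *best, cval=cval)
    sim = _ncc(reference, registered)
    if identity_sim >= sim:
        return RegistrationResult(RigidTransform(), target.copy(),
                                  identity_sim)
    return RegistrationResult(RigidTransform(*best), registered, sim)
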