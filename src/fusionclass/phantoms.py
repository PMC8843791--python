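"""Synthetic paired-modality tumor phantoms.

Every downstream stage (enhancement, registration, fusion, feature
extraction, classification) is testable without external data by generating
labeled pairs of images of the same scene:

* an *MRI-like* channel — sharp tumor boundary, moderate contrast, fine
  Gaussian texture noise;
* a *SPECT-like* channel — the same activity region at high contrast but
  blurred (low spatial resolution) with coarser noise.

The tumor boundary is a star-shaped polar curve

    r(theta) = base_radius * (1 + amplitude * sin(lobes * theta + phase))

so the two classes differ by boundary morphology: benign phantoms are
near-circular (amplitude <= 0.05), malignant ones spiculated
(amplitude >= 0.25).  Phantoms may carry 1-5 connected components (a main
lesion plus small satellite lesions) so per-component feature aggregation
is exercised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

BENIGN = "benign"
MALIGNANT = "malignant"

#: Flat background intensity of every rendered channel.
BACKGROUND = 0.1
#: Std of the fine texture noise on the MRI-like channel.
MRI_TEXTURE_SIGMA = 0.08
#: Gaussian blur applied to the SPECT-like activity map (px).
SPECT_BLUR_SIGMA = 4.0
#: Std of the coarse (low-frequency) noise on the SPECT-like channel.
SPECT_NOISE_SIGMA = 0.05
#: Spatial scale of the coarse SPECT noise (px).
SPECT_NOISE_BLUR = 2.0

#: Default per-modality (foreground, background) intensities.
DEFAULT_CONTRAST = {"mri": (0.55, BACKGROUND), "spect": (0.95, BACKGROUND)}


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom pair (before noise realization)."""

    label: str
    image_size: tuple[int, int] = (128, 128)
    center: tuple[float, float] = (64.0, 64.0)
    base_radius: float = 20.0
    spiculation_amplitude: float = 0.0
    spiculation_lobes: int = 8
    n_components: int = 1
    noise_sigma: float = 0.02
    modality_contrast: dict = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST)
    )

    def validate(self) -> None:
        if self.label not in (BENIGN, MALIGNANT):
            raise ValueError(f"unknown label {self.label!r}")
        rows, cols = self.image_size
        if rows <= 0 or cols <= 0:
            raise ValueError("image_size must be positive")
        if not (0.0 <= self.spiculation_amplitude < 1.0):
            raise ValueError("spiculation_amplitude must be in [0, 1)")
        if self.base_radius < 0:
            raise ValueError("base_radius must be >= 0")
        if self.base_radius >= min(self.image_size) / 4:
            raise ValueError("base_radius must be < min(image_size)/4")
        if self.label == BENIGN and self.spiculation_amplitude > 0.05:
            raise ValueError("benign specs require spiculation_amplitude <= 0.05")
        if self.label == MALIGNANT and 0 < self.base_radius and \
                self.spiculation_amplitude < 0.25:
            raise ValueError("malignant specs require spiculation_amplitude >= 0.25")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class LabeledPair:
    """One generated phantom: both channels, ground-truth mask, and label."""

    mri: np.ndarray
    spect: np.ndarray
    truth_mask: np.ndarray
    label: str
    spec: PhantomSpec
    seed: int


def _star_mask(shape, center, radius, amplitude, lobes, phase) -> np.ndarray:
    """Rasterize the star-shaped polar region r(theta)."""
    if radius <= 0:
        return np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    boundary = radius * (1.0 + amplitude * np.sin(lobes * theta + phase))
    return rr <= boundary


def _render_masks(spec: PhantomSpec, rng: np.random.Generator):
    """Main lesion plus satellite lesions; returns the union mask."""
    shape = spec.image_size
    phase = rng.uniform(0.0, 2.0 * math.pi)
    mask = _star_mask(shape, spec.center, spec.base_radius,
                      spec.spiculation_amplitude, spec.spiculation_lobes, phase)
    if spec.base_radius <= 0:
        return np.zeros(shape, dtype=bool)
    centers = [(spec.center, spec.base_radius * (1 + spec.spiculation_amplitude))]
    for _ in range(spec.n_components - 1):
        r_sat = rng.uniform(4.5, 8.0)
        for _attempt in range(50):
            cy = rng.uniform(r_sat + 2, shape[0] - r_sat - 2)
            cx = rng.uniform(r_sat + 2, shape[1] - r_sat - 2)
            if all(np.hypot(cy - c[0], cx - c[1]) > r + r_sat + 4
                   for c, r in centers):
                mask |= _star_mask(shape, (cy, cx), r_sat, 0.0, 0, 0.0)
                centers.append(((cy, cx), r_sat))
                break
    return mask


def generate_pair(spec: PhantomSpec, seed: int) -> LabeledPair:
    """Render one deterministic MRI-like / SPECT-like pair with known mask.

    The two channels share the exact same region geometry (pairs are
    generated pre-aligned); the truth mask is the noiseless rendering.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    mask = _render_masks(spec, rng)

    fg_m, bg_m = spec.modality_contrast["mri"]
    fg_s, bg_s = spec.modality_contrast["spect"]

    mri = bg_m + (fg_m - bg_m) * mask.astype(np.float64)
    mri += rng.normal(0.0, MRI_TEXTURE_SIGMA, size=mask.shape)
    if spec.noise_sigma > 0:
        mri += rng.normal(0.0, spec.noise_sigma, size=mask.shape)

    activity = bg_s + (fg_s - bg_s) * mask.astype(np.float64)
    spect = ndimage.gaussian_filter(activity, SPECT_BLUR_SIGMA)
    coarse = ndimage.gaussian_filter(rng.normal(size=mask.shape),
                                     SPECT_NOISE_BLUR)
    sd = coarse.std()
    if sd > 0:
        spect += coarse * (SPECT_NOISE_SIGMA / sd)
    if spec.noise_sigma > 0:
        spect += rng.normal(0.0, spec.noise_sigma, size=mask.shape)

    return LabeledPair(
        mri=np.clip(mri, 0.0, 1.0),
        spect=np.clip(spect, 0.0, 1.0),
        truth_mask=mask,
        label=spec.label,
        spec=spec,
        seed=seed,
    )


def _jittered_spec(label: str, rng: np.random.Generator,
                   image_size: tuple[int, int]) -> PhantomSpec:
    """Draw one class-respecting spec with jittered geometry."""
    rows, cols = image_size
    radius = rng.uniform(16.0, 24.0)
    cy = rows / 2 + rng.uniform(-6.0, 6.0)
    cx = cols / 2 + rng.uniform(-6.0, 6.0)
    if label == BENIGN:
        amp = rng.uniform(0.0, 0.04)
        lobes = int(rng.integers(4, 9))
    else:
        amp = rng.uniform(0.28, 0.42)
        lobes = int(rng.integers(6, 12))
    n_comp = int(rng.integers(1, 4))
    return PhantomSpec(
        label=label,
        image_size=image_size,
        center=(cy, cx),
        base_radius=radius,
        spiculation_amplitude=amp,
        spiculation_lobes=lobes,
        n_components=n_comp,
    )


def generate_dataset(n_per_class: int, seed: int,
                     image_size: tuple[int, int] = (128, 128)
                     ) -> list[LabeledPair]:
    """Generate a balanced dataset of ``2 * n_per_class`` labeled pairs.

    Per-pair seeds and spec jitters derive deterministically from the
    master seed; the same ``(n_per_class, seed)`` reproduces every image
    bit for bit.  Pairs alternate benign / malignant.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    master = np.random.default_rng(seed)
    pairs = []
    for _ in range(n_per_class):
        for label in (BENIGN, MALIGNANT):
            spec = _jittered_spec(label, master, image_size)
            pair_seed = int(master.integers(0, 2**31 - 1))
            pairs.append(generate_pair(spec, pair_seed))
    return pairs


def apply_known_transform(img: np.ndarray, dx: float, dy: float,
                          theta: float) -> np.ndarray:
    """Rigidly transform an image by a *known* amount (registration fixture).

    ``dx`` shifts along columns (x), ``dy`` along rows (y), ``theta`` rotates
    counterclockwise about the image center (degrees).  Bilinear
    interpolation; pixels entering from outside the frame take the
    background value.
    """
    from .preprocess import apply_rigid

    rows, cols = img.shape
    if abs(dx) >= cols or abs(dy) >= rows:
        raise ValueError("transform moves the image entirely out of frame")
    return apply_rigid(img, dx=dx, dy=dy, theta=theta, cval=BACKGROUND)


def write_pairs(pairs: list[LabeledPair], out_dir: str | Path) -> list[Path]:
    """Write pairs as 8-bit PNGs with JSON sidecars; returns written paths."""
    from .io import save_image, save_mask, write_json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, pair in enumerate(pairs):
        stem = f"pair_{i:04d}"
        paths = {
            "mri": out_dir / f"{stem}_mri.png",
            "spect": out_dir / f"{stem}_spect.png",
            "mask": out_dir / f"{stem}_mask.png",
            "json": out_dir / f"{stem}.json",
        }
        save_image(paths["mri"], pair.mri)
        save_image(paths["spect"], pair.spect)
        save_mask(paths["mask"], pair.truth_mask)
        sidecar = {"label": pair.label, "seed": pair.seed,
                   "spec": _spec_to_json(pair.spec)}
        write_json(paths["json"], sidecar)
        written.extend(paths.values())
    return written


def _spec_to_json(spec: PhantomSpec) -> dict:
    d = asdict(spec)
    d["image_size"] = list(spec.image_size)
    d["center"] = list(spec.center)
    d["modality_contrast"] = {k: list(v)
                              for k, v in spec.modality_contrast.items()}
    return d
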