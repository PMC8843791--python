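"""Tumor-region segmentation and the 30-value shape/texture feature vector.

Regions are segmented with a global Otsu threshold, labeled 8-connected,
hole-filled, and size-filtered.  Ten base features are computed per
connected component from its pixels, ordered boundary contour, and convex
hull:

    radius, texture, perimeter, area, smoothness, compactness,
    concavity, concave_points, symmetry, fractal_dimension

and aggregated across components into 30 values — the arithmetic *mean*,
the standard error (*se*), and the *worst* (mean of the three largest) of
each base feature.  Benign lesions (smooth, near-convex) and malignant
lesions (spiculated, concave) separate mainly on compactness, concavity,
concave points and smoothness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Point
from skimage import filters, measure

#: Connected components smaller than this are treated as noise.
MIN_COMPONENT_PX = 25
#: Hull depth (px) beyond which a boundary vertex counts as a concave point.
CONCAVE_DEPTH_PX = 1.5
#: Box sizes for the boundary box-counting dimension.
FRACTAL_BOX_SIZES = (2, 4, 8, 16, 32)

BASE_FEATURE_NAMES = (
    "radius", "texture", "perimeter", "area", "smoothness",
    "compactness", "concavity", "concave_points", "symmetry",
    "fractal_dimension",
)

#: Fixed 30-name order: all means, then standard errors, then worsts.
FEATURE_NAMES = tuple(
    f"{agg}_{base}"
    for agg in ("mean", "se", "worst")
    for base in BASE_FEATURE_NAMES
)


@dataclass
class Component:
    """One segmented connected component."""

    pixels: np.ndarray  # (n, 2) int row/col coordinates
    contour: np.ndarray  # (m, 2) ordered closed boundary pixel sequence
    mask: np.ndarray  # full-size boolean mask of this component


@dataclass
class RegionMask:
    """Binary segmentation plus its per-component decomposition."""

    mask: np.ndarray
    components: list

    def __len__(self) -> int:
        return len(self.components)

    @property
    def is_empty(self) -> bool:
        return len(self.components) == 0


@dataclass(frozen=True)
class BaseFeatures:
    radius: float
    texture: float
    perimeter: float
    area: float
    smoothness: float
    compactness: float
    concavity: float
    concave_points: float
    symmetry: float
    fractal_dimension: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in BASE_FEATURE_NAMES])


@dataclass
class FeatureVector:
    """The 30 aggregated values in :data:`FEATURE_NAMES` order."""

    values: np.ndarray

    @property
    def names(self) -> tuple:
        return FEATURE_NAMES

    def as_dict(self) -> dict:
        return dict(zip(FEATURE_NAMES, map(float, self.values)))


def segment(img: np.ndarray) -> RegionMask:
    """Otsu threshold -> 8-connected labeling -> size filter -> hole fill.

    Raises on a constant image (no threshold exists).  An image with no
    component surviving the 25 px size filter yields an *empty* RegionMask,
    not an error.
    """
    img = np.asarray(img, dtype=np.float64)
    if np.ptp(img) < 1e-12:
        raise ValueError("cannot threshold a constant image")
    thr = filters.threshold_otsu(img)
    binary = img > thr
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    components = []
    for lab in range(1, n + 1):
        comp_mask = ndimage.binary_fill_holes(labels == lab)
        if int(comp_mask.sum()) < MIN_COMPONENT_PX:
            continue
        pixels = np.argwhere(comp_mask)
        contour = trace_boundary(comp_mask)
        components.append(Component(pixels=pixels, contour=contour,
                                    mask=comp_mask))
    full = np.zeros(img.shape, dtype=bool)
    for comp in components:
        full |= comp.mask
    return RegionMask(mask=full, components=components)


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed boundary pixel sequence (Moore-neighbor tracing).

    Starts at the topmost-leftmost foreground pixel and walks the outer
    boundary clockwise; returns an (m, 2) array of row/col coordinates
    without repeating the start point.
    """
    mask = np.asarray(mask, dtype=bool)
    pts = np.argwhere(mask)
    if len(pts) == 0:
        raise ValueError("cannot trace the boundary of an empty mask")
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    start = tuple(pts[order[0]])
    # 8-neighborhood, clockwise starting from west
    nb = [(0, -1), (-1, -1), (-1, 0), (-1, 1),
          (0, 1), (1, 1), (1, 0), (1, -1)]
    rows, cols = mask.shape

    def inside(p):
        return 0 <= p[0] < rows and 0 <= p[1] < cols and mask[p]

    contour = [start]
    prev = (start[0], start[1] - 1)
    cur = start
    while True:
        d = (prev[0] - cur[0], prev[1] - cur[1])
        i = nb.index(d)
        nxt = None
        for k in range(1, 9):
            cand = (cur[0] + nb[(i + k) % 8][0], cur[1] + nb[(i + k) % 8][1])
            if inside(cand):
                nxt = cand
                prev = (cur[0] + nb[(i + k - 1) % 8][0],
                        cur[1] + nb[(i + k - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            break
        cur = nxt
        if cur == start and len(contour) > 1:
            break
        contour.append(cur)
    return np.array(contour, dtype=np.float64)


def _hull_depths(contour: np.ndarray) -> np.ndarray:
    """Distance of each boundary vertex to the convex-hull boundary."""
    hull = MultiPoint([tuple(p) for p in contour]).convex_hull
    boundary = hull.exterior if hull.geom_type == "Polygon" else hull
    return np.array([boundary.distance(Point(p)) for p in contour])


def _symmetry(pixels: np.ndarray) -> float:
    """Mean relative imbalance of chord halves perpendicular to the major axis."""
    coords = pixels.astype(np.float64)
    centered = coords - coords.mean(axis=0)
    cov = np.cov(centered.T)
    _, eigvecs = np.linalg.eigh(cov)  # ascending eigenvalues
    major = eigvecs[:, -1]
    minor = eigvecs[:, 0]
    u = centered @ major  # position along the major axis
    v = centered @ minor  # signed offset from the axis
    stations = np.round(u).astype(int)
    diffs, sums = [], []
    for s in np.unique(stations):
        vs = v[stations == s]
        above = max(vs.max(), 0.0)
        below = max(-vs.min(), 0.0)
        if above + below > 0:
            diffs.append(abs(above - below))
            sums.append(above + below)
    if not sums:
        return 0.0
    return float(np.mean(diffs) / np.mean(sums))


def _fractal_dimension(contour: np.ndarray) -> float:
    """Box-counting dimension of the boundary point set, minus 1."""
    pts = contour - contour.min(axis=0)
    sizes = np.array(FRACTAL_BOX_SIZES, dtype=np.float64)
    counts = []
    for s in sizes:
        boxes = np.unique(np.floor(pts / s), axis=0)
        counts.append(len(boxes))
    slope = np.polyfit(np.log(1.0 / sizes), np.log(counts), 1)[0]
    return float(slope - 1.0)


def component_features(img: np.ndarray, component: Component) -> BaseFeatures:
    """The 10 base features of one segmented component.

    * radius — mean centroid-to-boundary distance (px)
    * texture — std of source-image intensities over the component pixels
    * perimeter — Crofton perimeter estimate of the component mask (px)
    * area — pixel count (px^2)
    * smoothness — mean local radial deviation |r_i - (r_{i-1}+r_{i+1})/2|
      normalized by the mean radius
    * compactness — perimeter^2 / (4 pi area) - 1 (about 0 for a disk)
    * concavity — mean convex-hull depth of boundary points / mean radius
    * concave_points — boundary vertices deeper than 1.5 px inside the hull
    * symmetry — chord-imbalance about the major axis
    * fractal_dimension — boundary box-counting dimension - 1
    """
    img = np.asarray(img, dtype=np.float64)
    pixels = component.pixels
    contour = component.contour
    centroid = pixels.mean(axis=0)
    radii = np.hypot(contour[:, 0] - centroid[0], contour[:, 1] - centroid[1])
    mean_radius = float(radii.mean())
    area = float(len(pixels))

    rp = measure.regionprops(component.mask.astype(np.uint8))[0]
    perimeter = float(rp.perimeter_crofton)

    neighbors = (np.roll(radii, 1) + np.roll(radii, -1)) / 2.0
    smoothness = float(np.mean(np.abs(radii - neighbors)) / mean_radius)

    compactness = float(perimeter**2 / (4.0 * np.pi * area) - 1.0)

    depths = _hull_depths(contour)
    concavity = float(depths.mean() / mean_radius)
    concave_points = float(np.count_nonzero(depths > CONCAVE_DEPTH_PX))

    texture = float(img[pixels[:, 0].astype(int), pixels[:, 1].astype(int)].std())

    return BaseFeatures(
        radius=mean_radius,
        texture=texture,
        perimeter=perimeter,
        area=area,
        smoothness=smoothness,
        compactness=compactness,
        concavity=concavity,
        concave_points=concave_points,
        symmetry=_symmetry(pixels),
        fractal_dimension=_fractal_dimension(contour),
    )


def feature_vector(img: np.ndarray, mask: RegionMask) -> FeatureVector:
    """Aggregate per-component base features into the 30-value vector.

    mean = arithmetic mean over components; se = sample std / sqrt(n)
    (0 for a single component); worst = mean of the three largest values
    (all values when fewer than three components).
    """
    if mask.is_empty:
        raise ValueError("cannot extract features from an empty mask")
    per_comp = np.vstack([component_features(img, c).as_array()
                          for c in mask.components])
    n = per_comp.shape[0]
    means = per_comp.mean(axis=0)
    if n > 1:
        ses = per_comp.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        ses = np.zeros(per_comp.shape[1])
    k = min(3, n)
    worsts = np.sort(per_comp, axis=0)[-k:].mean(axis=0)
    return FeatureVector(values=np.concatenate([means, ses, worsts]))
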