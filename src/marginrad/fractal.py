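"""Fractal-based margin features: box-counting dimension, lacunarity and
blanket-method fractal signature dissimilarity (FSD).

* The box-counting dimension is computed on the 3D boundary-voxel set of
  the tumor mask — the margin's geometry, not the filled solid.
* Lacunarity is the gliding-box statistic var/mean^2 + 1 of box mass,
  averaged over box sizes; 1 for translation-homogeneous solids, larger
  for gappy or spiculated patterns.
* The blanket method grows upper/lower envelopes around the intensity
  surface of the maximal-area axial slice; the scale-indexed surface area
  A(eps) yields a fractal signature (local log-log slope), and FSD is
  defined here as the mean absolute signature difference between the
  margin rim and the tumor core — a single-image margin-vs-interior
  texture contrast.  (The published blanket signature compares two
  images; the rim/core reading is this package's adaptation for a
  per-tumor feature and is the largest interpretive choice in the
  package; see docs/methods.md.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ImageVolume, ROIMask, boundary_voxels, max_area_axial_slice

__all__ = [
    "FractalFeatures",
    "InsufficientScaleError",
    "box_counting_dimension",
    "lacunarity",
    "blanket_surface_area",
    "fractal_signature",
    "fsd_blanket",
    "compute_fractal",
]


class InsufficientScaleError(ValueError):
    """Too few usable scales for a log-log fit."""


DEFAULT_EPSILONS: tuple[int, ...] = tuple(range(1, 9))
DEFAULT_BOX_SIZES: tuple[int, ...] = (2, 4, 8)
DEFAULT_RIM_WIDTH = 3.0  # pixels

_CROSS2D = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)  # 4-neighbours


@dataclass(frozen=True)
class FractalFeatures:
    fractal_dimension: float
    lacunarity: float
    fsd_blanket: float
    fit_diagnostics: dict = field(default_factory=dict, compare=False)
    degenerate_fsd: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "fractal.dimension": self.fractal_dimension,
            "fractal.lacunarity": self.lacunarity,
            "fractal.fsd_blanket": self.fsd_blanket,
        }


def box_counting_dimension(points: np.ndarray) -> tuple[float, dict]:
    """Box-counting dimension of an integer coordinate set.

    Counts occupied boxes N(s) for dyadic sizes s = 1, 2, 4, ... up to
    half the bounding-box extent (at least 3 sizes required); the
    dimension is minus the slope of the least-squares fit of log N(s) on
    log s.  Returns ``(dimension, diagnostics)`` where diagnostics carry
    the sizes, counts and R^2 of the fit.
    """
    points = np.asarray(points, dtype=np.int64)
    if points.ndim != 2 or len(points) < 16:
        raise InsufficientScaleError(f"need >= 16 points, got {len(points)}")
    points = points - points.min(axis=0)
    extent = int(points.max() + 1)
    sizes = []
    s = 1
    while s <= extent / 2:
        sizes.append(s)
        s *= 2
    if len(sizes) < 3:
        raise InsufficientScaleError(
            f"bounding-box extent {extent} allows only {len(sizes)} box sizes; need >= 3"
        )
    counts = [len(np.unique(points // s, axis=0)) for s in sizes]
    log_s, log_n = np.log(sizes), np.log(counts)
    slope, intercept = np.polyfit(log_s, log_n, 1)
    resid = log_n - (slope * log_s + intercept)
    ss_tot = float(((log_n - log_n.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return -float(slope), {"sizes": sizes, "counts": counts, "r_squared": r2}


def _gliding_box_masses(grid: np.ndarray, r: int) -> np.ndarray:
    """Sums over all r^3 boxes fully inside the grid (stride 1)."""
    c = grid.astype(np.float64)
    for ax in range(3):
        c = np.cumsum(c, axis=ax)
    c = np.pad(c, ((1, 0), (1, 0), (1, 0)))
    out = (
        c[r:, r:, r:] - c[:-r, r:, r:] - c[r:, :-r, r:] - c[r:, r:, :-r]
        + c[:-r, :-r, r:] + c[:-r, r:, :-r] + c[r:, :-r, :-r] - c[:-r, :-r, :-r]
    )
    return out


def lacunarity(mask: ROIMask, box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES) -> float:
    """Mean gliding-box lacunarity of the mask over the given box sizes.

    For each size r, box mass is summed over every r^3 box fully inside
    the mask's bounding box; Lambda(r) = var(mass)/mean(mass)^2 + 1.
    """
    fg = mask.data
    coords = np.argwhere(fg)
    lo, hi = coords.min(axis=0), coords.max(axis=0) + 1
    bbox = fg[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if min(bbox.shape) < 8:
        raise InsufficientScaleError(
            f"mask bounding box {bbox.shape} must be >= 8 in every axis"
        )
    lams = []
    for r in box_sizes:
        masses = _gliding_box_masses(bbox, r).ravel()
        mean = masses.mean()
        lams.append(float(masses.var() / mean**2 + 1.0))
    return float(np.mean(lams))


def blanket_surface_area(
    image2d: np.ndarray, epsilons: tuple[int, ...] = DEFAULT_EPSILONS
) -> np.ndarray:
    """Blanket-method surface area series A(eps) of a 2D intensity surface.

    Upper blanket u and lower blanket b start at the image; at each step
    u grows by 1 or to the maximum over 4-neighbours, b symmetrically
    shrinks.  A(eps) = sum(u_eps - b_eps) / (2 eps).  For a flat image
    A(eps) equals the pixel count exactly.
    """
    img = np.asarray(image2d, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 16:
        raise InsufficientScaleError(f"need a 2D grid >= 16x16, got {img.shape}")
    u = img.copy()
    b = img.copy()
    areas = np.empty(len(epsilons))
    for i, eps in enumerate(epsilons):
        # 'nearest' replication makes out-of-grid neighbours neutral
        u = np.maximum(u + 1.0, ndimage.maximum_filter(u, footprint=_CROSS2D, mode="nearest"))
        b = np.minimum(b - 1.0, ndimage.minimum_filter(b, footprint=_CROSS2D, mode="nearest"))
        areas[i] = (u - b).sum() / (2.0 * eps)
    return areas


def fractal_signature(areas: np.ndarray, epsilons: tuple[int, ...] = DEFAULT_EPSILONS) -> np.ndarray:
    """Scale-indexed fractal signature S(eps) = 2 - dlog A / dlog eps, eps >= 2."""
    eps = np.asarray(epsilons, dtype=np.float64)
    log_a, log_e = np.log(areas), np.log(eps)
    return 2.0 - np.diff(log_a) / np.diff(log_e)


def fsd_blanket(
    volume: ImageVolume,
    mask: ROIMask,
    rim_width: float = DEFAULT_RIM_WIDTH,
    epsilons: tuple[int, ...] = DEFAULT_EPSILONS,
) -> tuple[float, bool]:
    """Fractal signature dissimilarity between margin rim and tumor core.

    On the maximal-area axial slice the ROI is split by the Euclidean
    distance transform into a rim (within ``rim_width`` pixels of the
    in-plane boundary) and a core.  Each region's intensity patch (other
    pixels held at the region mean to avoid edge artefacts) gets a blanket
    signature; FSD is the mean absolute signature difference.  An empty
    rim or core yields ``(0.0, True)`` (degenerate).
    """
    k, sl = max_area_axial_slice(mask)
    coords = np.argwhere(sl)
    lo, hi = coords.min(axis=0), coords.max(axis=0) + 1
    roi = sl[lo[0]:hi[0], lo[1]:hi[1]]
    intensity = volume.data[lo[0]:hi[0], lo[1]:hi[1], k]
    if min(roi.shape) < 16:
        raise InsufficientScaleError(
            f"maximal-area slice ROI {roi.shape} must be >= 16x16"
        )
    dist = ndimage.distance_transform_edt(roi)
    rim = roi & (dist <= rim_width)
    core = roi & (dist > rim_width)
    if not rim.any() or not core.any():
        return 0.0, True
    sigs = []
    for region in (rim, core):
        patch = np.where(region, intensity, intensity[region].mean())
        sigs.append(fractal_signature(blanket_surface_area(patch, epsilons), epsilons))
    return float(np.mean(np.abs(sigs[0] - sigs[1]))), False


def compute_fractal(
    volume: ImageVolume,
    mask: ROIMask,
    rim_width: float = DEFAULT_RIM_WIDTH,
    epsilons: tuple[int, ...] = DEFAULT_EPSILONS,
    box_sizes: tuple[int, ...] = DEFAULT_BOX_SIZES,
) -> FractalFeatures:
    """All three fractal features of a volume/mask pair."""
    dim, diag = box_counting_dimension(boundary_voxels(mask))
    lac = lacunarity(mask, box_sizes=box_sizes)
    fsd, degenerate = fsd_blanket(volume, mask, rim_width=rim_width, epsilons=epsilons)
    return FractalFeatures(
        fractal_dimension=dim,
        lacunarity=lac,
        fsd_blanket=fsd,
        fit_diagnostics=diag,
        degenerate_fsd=degenerate,
    )
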