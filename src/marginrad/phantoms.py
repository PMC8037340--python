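"""Digital phantoms with known geometry for exercising the feature extractors.

The phantoms stand in for resected lung adenocarcinomas on CT: smooth
spheres/ellipsoids/cuboids for calibration, plus spiculated (sphere with
radial spikes) and lobulated (union of overlapping spheres) tumors whose
margin irregularity is controlled by construction.  All sizes are in voxel
units; physical spacing only enters through the returned containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io import GeometryError, ImageVolume, ROIMask

__all__ = ["PhantomSpec", "make_phantom", "fibonacci_directions"]

_KINDS = ("sphere", "ellipsoid", "cuboid", "spiculated", "lobulated")
_TEXTURES = ("constant", "gaussian_noise", "gradient")

#: lung-window-like background intensity (HU-like units)
BACKGROUND_HU = -800.0
#: default soft-tissue interior intensity
INTERIOR_HU = 60.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one analytic phantom.

    Size parameters are voxel units.  ``spike_length`` is measured from the
    sphere surface outward; spikes have a square ``spike_width`` cross
    section and point along seeded quasi-uniform directions, so the same
    spec and seed always digitize to the same mask.
    """

    kind: str = "sphere"
    radius: float = 10.0
    semi_axes: tuple[float, float, float] = (10.0, 8.0, 6.0)
    edges: tuple[float, float, float] = (10.0, 10.0, 10.0)
    n_spikes: int = 0
    spike_length: float = 5.0
    spike_width: float = 3.0
    n_lobes: int = 3
    lobe_radius: float | None = None
    lobe_offset: float | None = None
    texture: str = "constant"
    texture_mean: float = INTERIOR_HU
    texture_sd: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {_KINDS}")
        if self.texture not in _TEXTURES:
            raise ValueError(f"unknown texture {self.texture!r}; choose from {_TEXTURES}")
        sizes = {"radius": self.radius, **{f"semi_axis[{i}]": a for i, a in enumerate(self.semi_axes)},
                 **{f"edge[{i}]": e for i, e in enumerate(self.edges)}}
        for name, v in sizes.items():
            if v < 2:
                raise ValueError(f"{name} must be >= 2 voxels, got {v}")
        if self.n_spikes < 0 or self.n_lobes < 1:
            raise ValueError("n_spikes must be >= 0 and n_lobes >= 1")

    def max_extent(self) -> float:
        """Largest half-extent of the analytic shape, in voxels."""
        if self.kind == "sphere":
            return self.radius
        if self.kind == "ellipsoid":
            return max(self.semi_axes)
        if self.kind == "cuboid":
            return max(self.edges) / 2.0
        if self.kind == "spiculated":
            return self.radius + (self.spike_length if self.n_spikes else 0.0)
        lobe_r = self.lobe_radius if self.lobe_radius is not None else 0.55 * self.radius
        lobe_off = self.lobe_offset if self.lobe_offset is not None else 0.75 * self.radius
        return max(self.radius, lobe_off + lobe_r)


def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _solid_mask(spec: PhantomSpec, coords: tuple[np.ndarray, np.ndarray, np.ndarray]) -> np.ndarray:
    x, y, z = coords
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "sphere":
        return x * x + y * y + z * z <= spec.radius**2
    if spec.kind == "ellipsoid":
        a, b, c = spec.semi_axes
        return (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    if spec.kind == "cuboid":
        ex, ey, ez = spec.edges
        return (np.abs(x) <= ex / 2) & (np.abs(y) <= ey / 2) & (np.abs(z) <= ez / 2)
    if spec.kind == "spiculated":
        mask = x * x + y * y + z * z <= spec.radius**2
        if spec.n_spikes == 0:
            return mask
        # seeded rotation of a low-discrepancy direction set: reproducible
        # geometry even for small n_spikes
        rot = Rotation.random(random_state=np.random.RandomState(spec.seed))
        dirs = fibonacci_directions(spec.n_spikes) @ rot.as_matrix().T
        pts = np.stack([x, y, z], axis=-1)
        half_w = spec.spike_width / 2.0
        reach = spec.radius + spec.spike_length
        for d in dirs:
            # orthonormal frame (d, u, v); square cross-section spike
            ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            u = np.cross(d, ref)
            u /= np.linalg.norm(u)
            v = np.cross(d, u)
            t = pts @ d
            spike = (
                (t >= 0)
                & (t <= reach)
                & (np.abs(pts @ u) <= half_w)
                & (np.abs(pts @ v) <= half_w)
            )
            mask |= spike
        return mask
    # lobulated: union of overlapping spheres around the main one
    lobe_r = spec.lobe_radius if spec.lobe_radius is not None else 0.55 * spec.radius
    lobe_off = spec.lobe_offset if spec.lobe_offset is not None else 0.75 * spec.radius
    rot = Rotation.random(random_state=np.random.RandomState(spec.seed))
    dirs = fibonacci_directions(spec.n_lobes) @ rot.as_matrix().T
    mask = x * x + y * y + z * z <= spec.radius**2
    for d in dirs:
        cx, cy, cz = d * lobe_off
        mask |= (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= lobe_r**2
    return mask


def make_phantom(
    spec: PhantomSpec,
    grid_shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[ImageVolume, ROIMask]:
    """Digitize *spec* onto a grid: voxel centers inside the analytic shape
    become mask foreground; intensities follow the texture rule with a
    constant lung-like background.

    Raises :class:`GeometryError` when the shape (plus a 2-voxel margin)
    does not fit inside ``grid_shape``.
    """
    shape = tuple(int(s) for s in grid_shape)
    center = (np.array(shape) - 1) / 2.0
    extent = spec.max_extent()
    for ax in range(3):
        if extent + 2.0 > min(center[ax], shape[ax] - 1 - center[ax]) + 0.5:
            raise GeometryError(
                f"phantom extent {extent:.1f} vox (+2 margin) does not fit in grid {shape}"
            )
    idx = np.indices(shape, dtype=np.float64)
    coords = tuple(idx[ax] - center[ax] for ax in range(3))
    fg = _solid_mask(spec, coords)

    rng = np.random.default_rng(spec.seed + 1)  # texture stream, independent of geometry
    data = np.full(shape, BACKGROUND_HU, dtype=np.float64)
    if spec.texture == "constant":
        data[fg] = spec.texture_mean
    elif spec.texture == "gaussian_noise":
        data[fg] = rng.normal(spec.texture_mean, spec.texture_sd, size=int(fg.sum()))
    else:  # gradient along x across the shape extent
        ramp = spec.texture_mean + (coords[0] / max(extent, 1.0)) * 50.0
        data[fg] = ramp[fg]

    volume = ImageVolume(data=data, spacing=spacing)
    mask = ROIMask(data=fg, spacing=spacing)
    return volume, mask
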