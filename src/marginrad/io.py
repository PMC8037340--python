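"""Volume and ROI-mask containers plus NIfTI/NRRD input-output.

Grids are indexed ``(x, y, z)`` with ``z`` the axial (slice) axis.
Coordinates are 0-based voxel indices; physical positions are
``index * spacing`` in millimetres.  Affine orientation beyond the voxel
spacing is deliberately ignored: masks are required to live on the same
grid as their volume, which is all the feature extractors need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "ROIMask",
    "GeometryError",
    "EmptyROIError",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "max_area_axial_slice",
    "boundary_voxels",
]


class GeometryError(ValueError):
    """Grid shape / spacing inconsistency between a volume and a mask."""


class EmptyROIError(ValueError):
    """A mask with no foreground voxels."""


# 26-connectivity structuring element for component labelling
_CONN26 = np.ones((3, 3, 3), dtype=bool)
# 6-connectivity (face neighbours) for boundary detection
_CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar CT-like image with per-axis physical spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise GeometryError(f"volume must be 3D, got {data.ndim}D")
        if min(data.shape) < 1:
            raise GeometryError(f"all dimensions must be >= 1, got {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume intensities must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise GeometryError(f"spacing must be three positive finite values, got {spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class ROIMask:
    """Binary tumor mask on the same grid as its paired :class:`ImageVolume`.

    ``data`` holds every foreground voxel (used for intensity features);
    ``largest`` holds the largest 26-connected component (used for shape
    features, so that degenerate multi-component inputs stay deterministic).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    n_components: int = field(init=False)
    largest: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        data = np.asarray(self.data) > 0
        if data.ndim != 3:
            raise GeometryError(f"mask must be 3D, got {data.ndim}D")
        if not data.any():
            raise EmptyROIError("mask has no foreground voxels")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise GeometryError(f"spacing must be three positive finite values, got {spacing}")
        labels, n = ndimage.label(data, structure=_CONN26)
        if n > 1:
            sizes = ndimage.sum_labels(data, labels, index=np.arange(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            largest = labels == keep
            warnings.warn(
                f"mask has {n} connected components; shape features use the "
                f"largest ({int(sizes.max())} voxels)",
                stacklevel=3,
            )
        else:
            largest = data
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "n_components", int(n))
        object.__setattr__(self, "largest", largest)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def _read_any(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI-1 (.nii/.nii.gz) or NRRD (.nrrd) file to (x,y,z) array + spacing."""
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith(".nrrd"):
        import SimpleITK as sitk  # optional format, imported lazily

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        if arr.ndim != 3:
            raise GeometryError(f"expected a 3D payload, got {arr.ndim}D in {path}")
        return np.ascontiguousarray(arr.transpose(2, 1, 0)), tuple(img.GetSpacing())
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise GeometryError(f"expected a 3D payload, got {arr.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    return np.asarray(arr), tuple(float(z) for z in zooms)


def load_volume(path) -> ImageVolume:
    """Load a CT volume from NIfTI-1 (or NRRD); spacing is taken from the header."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    arr, spacing = _read_any(path)
    return ImageVolume(data=arr.astype(np.float64), spacing=spacing)


def load_mask(path, volume: ImageVolume) -> ROIMask:
    """Load a tumor mask aligned to *volume*; any value > 0 is foreground."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    arr, _ = _read_any(path)
    if arr.shape != volume.shape:
        raise GeometryError(
            f"mask shape {arr.shape} does not match volume shape {volume.shape}"
        )
    return ROIMask(data=arr, spacing=volume.spacing)


def save_volume(volume: ImageVolume, path) -> None:
    """Write a volume to NIfTI-1 with a diagonal spacing affine."""
    import nibabel as nib

    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data, affine), str(path))


def save_mask(mask: ROIMask, path) -> None:
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), affine), str(path))


def max_area_axial_slice(mask: ROIMask, component: str = "largest") -> tuple[int, np.ndarray]:
    """Axial (z) slice maximizing in-plane foreground area in mm^2.

    Ties are broken toward the smallest slice index.  Returns
    ``(slice_index, 2D boolean image)`` indexed ``(x, y)``.
    """
    grid = mask.largest if component == "largest" else mask.data
    counts = grid.sum(axis=(0, 1))  # per-z voxel counts; area = count * sx * sy
    k = int(np.argmax(counts))  # argmax takes the first maximum -> smallest index
    if counts[k] == 0:
        raise EmptyROIError("mask has no foreground voxels")
    return k, grid[:, :, k].copy()


def boundary_voxels(mask: ROIMask, component: str = "largest") -> np.ndarray:
    """Foreground voxels with at least one background 6-neighbour.

    Voxels on the grid edge count their out-of-grid neighbours as background.
    Returns an (n, 3) integer coordinate array.
    """
    grid = mask.largest if component == "largest" else mask.data
    interior = ndimage.binary_erosion(grid, structure=_CONN6, border_value=0)
    return np.argwhere(grid & ~interior)
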