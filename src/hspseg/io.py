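"""NIfTI input/output and the basic spatial containers.

All voxel coordinates in this package are 0-based ``(i, j, k)`` array
indices in storage order; the third axis is the slice axis. Orientation
matrices (affines) are carried through opaquely and never used for
resampling — every algorithm operates on the native voxel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "ContractError",
    "DataError",
    "DimensionalityError",
    "Volume3D",
    "Mask3D",
    "SeedPoint",
    "read_volume",
    "read_mask",
    "write_mask",
    "write_volume",
    "sphere_mask",
]


class ContractError(ValueError):
    """An argument violates a documented precondition."""


class DataError(ValueError):
    """Loaded data violates an invariant (e.g. non-finite voxels)."""


class DimensionalityError(DataError):
    """An image is not a 3D (or squeezable single-frame 4D) volume."""


@dataclass(eq=False)
class Volume3D:
    """A 3D scalar image with anisotropic voxel spacing in mm.

    Parameters
    ----------
    data : ndarray
        3D array of finite intensities (arbitrary units).
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all strictly positive.
    affine : ndarray, optional
        4x4 voxel-to-world matrix, passed through to any file written
        from this volume. ``None`` means a diagonal affine built from
        ``spacing``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (0.45, 0.45, 0.9)
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise DimensionalityError(
                f"expected a 3D volume, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise DataError("volume contains non-finite voxel values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be three positive mm values, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(eq=False)
class Mask3D:
    """A binary mask on the grid of a parent :class:`Volume3D`."""

    data: np.ndarray
    spacing: Tuple[float, float, float] = (0.45, 0.45, 0.9)
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise DimensionalityError(f"expected a 3D mask, got shape {arr.shape}")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise DataError("mask values must be 0/1")
            arr = arr.astype(bool)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class SeedPoint:
    """A voxel-coordinate seed, either user-placed or window-corrected."""

    i: int
    j: int
    k: int
    kind: str = "manual"  # "manual" | "corrected"

    def __post_init__(self) -> None:
        if self.kind not in ("manual", "corrected"):
            raise ContractError(f"seed kind must be manual|corrected, got {self.kind!r}")

    def as_tuple(self) -> Tuple[int, int, int]:
        return (int(self.i), int(self.j), int(self.k))

    def check_in_bounds(self, shape: Tuple[int, int, int]) -> None:
        for idx, n in zip(self.as_tuple(), shape):
            if not (0 <= idx < n):
                raise ContractError(
                    f"seed point {self.as_tuple()} is outside the volume of shape {tuple(shape)}"
                )


def _default_affine(spacing: Tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def _load_3d(path) -> tuple[np.ndarray, Tuple[float, float, float], np.ndarray]:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise DimensionalityError(
            f"{path}: expected a 3D image (or single-frame 4D), got shape {arr.shape}"
        )
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(arr, dtype=np.float64), zooms, img.affine


def read_volume(path) -> Volume3D:
    """Load a 3D NIfTI volume, taking voxel spacing from the header.

    Raises
    ------
    DimensionalityError
        If the image is not 3D (single-frame 4D inputs are squeezed).
    DataError
        If any voxel is NaN or infinite.
    """
    arr, zooms, affine = _load_3d(path)
    return Volume3D(data=arr, spacing=zooms, affine=affine)


def read_mask(path, reference: Optional[Volume3D] = None) -> Mask3D:
    """Load a binary NIfTI mask; check its shape against ``reference`` if given."""
    arr, zooms, affine = _load_3d(path)
    if not np.all(np.isfinite(arr)):
        raise DataError(f"{path}: mask contains non-finite values")
    if not np.all(np.isin(np.unique(arr), (0, 1))):
        raise DataError(f"{path}: mask payload is not 0/1")
    mask = Mask3D(data=arr.astype(bool), spacing=zooms, affine=affine)
    if reference is not None and mask.shape != reference.shape:
        raise ContractError(
            f"mask shape {mask.shape} does not match reference shape {reference.shape}"
        )
    return mask


def write_mask(mask: Mask3D, path, reference: Optional[Volume3D] = None) -> None:
    """Write a mask as a uint8 0/1 NIfTI with the reference's spatial metadata."""
    if reference is not None and mask.shape != reference.shape:
        raise ContractError(
            f"mask shape {mask.shape} does not match reference shape {reference.shape}"
        )
    spacing = reference.spacing if reference is not None else mask.spacing
    affine = reference.affine if reference is not None else mask.affine
    if affine is None:
        affine = _default_affine(spacing)
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def write_volume(volume: Volume3D, path) -> None:
    """Write a volume as float32 NIfTI with its spacing in the header."""
    affine = volume.affine if volume.affine is not None else _default_affine(volume.spacing)
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def sphere_mask(
    reference: Volume3D, center: Tuple[int, int, int], radius_mm: float
) -> Mask3D:
    """Rasterize a sphere (voxel-index center, mm radius) by voxel-center inclusion.

    Used for muscle-reference ROIs specified as ``i,j,k,r_mm`` instead of a
    mask file.
    """
    if radius_mm <= 0:
        raise ContractError(f"sphere radius must be positive, got {radius_mm}")
    SeedPoint(*[int(c) for c in center]).check_in_bounds(reference.shape)
    grids = np.ogrid[[slice(0, n) for n in reference.shape]]
    dist2 = sum(
        ((g - c) * s) ** 2 for g, c, s in zip(grids, center, reference.spacing)
    )
    return Mask3D(
        data=dist2 <= radius_mm**2,
        spacing=reference.spacing,
        affine=reference.affine,
    )
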