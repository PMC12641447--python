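"""Voxel volumes with physical spacing.

A :class:`VoxelVolume` is the carrier for every volumetric mask in the
pipeline: binary vessel masks, integer-labelled lesion volumes and binary
ventricle masks.  Voxel indices are 0-based; the world coordinate of voxel
``(i, j, k)`` is ``index * spacing + origin`` (mm).  NIfTI round-tripping
goes through nibabel with a diagonal affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, InvalidParameterError

__all__ = ["VoxelVolume", "read_nifti", "write_nifti"]


@dataclass
class VoxelVolume:
    """A 3-D labelled or binary grid with physical spacing.

    Parameters
    ----------
    grid
        3-D integer (label) or boolean array; 0 / False is background.
    spacing
        Voxel edge length per axis in mm, strictly positive.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise InvalidParameterError(f"grid must be 3-D, got ndim={self.grid.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.grid.dtype != bool and self.grid.min() < 0:
            raise InvalidParameterError("label values must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (1 mL = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    def world(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def index(self, points: np.ndarray) -> np.ndarray:
        """Nearest voxel index of world points (mm), shape (n, 3); not bounds-checked."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.rint((pts - np.asarray(self.origin)) / np.asarray(self.spacing)).astype(int)

    def same_grid(self, other: "VoxelVolume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def require_same_grid(self, other: "VoxelVolume", what: str = "volume") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} grid mismatch: shape {self.shape} vs {other.shape}, "
                f"spacing {self.spacing} vs {other.spacing}, origin {self.origin} vs {other.origin}"
            )


def read_nifti(path) -> VoxelVolume:
    """Load a NIfTI volume; spacing from the header zooms, origin from the affine translation."""
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj)
    if grid.ndim != 3:
        raise InvalidParameterError(f"expected a 3-D NIfTI, got shape {grid.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in np.asarray(img.affine)[:3, 3])
    if np.issubdtype(grid.dtype, np.floating):
        grid = np.rint(grid).astype(np.int32)
    return VoxelVolume(grid=grid, spacing=spacing, origin=origin)


def write_nifti(volume: VoxelVolume, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    data = volume.grid.astype(np.int16 if volume.grid.dtype == bool else volume.grid.dtype)
    nib.save(nib.Nifti1Image(data, affine), str(path))
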