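"""3-D voxel lattices with an affine index-to-mm mapping.

A :class:`VoxelGrid` is the backbone of every spatial object in the
package: gray-matter density maps, binary region masks, integer label
maps and probabilistic templates are all grids over the same lattice.
The affine follows the NIfTI convention: homogeneous 4x4 matrix mapping
voxel indices ``(i, j, k)`` to RAS+ millimetre coordinates, so the
second axis is the anterior-posterior (y) axis with anterior positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "default_affine"]


def default_affine(shape: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """Isotropic RAS+ affine centring x/z on 0 mm and placing y so the
    grid spans mostly negative (posterior) coordinates, as in MNI space
    around the hippocampus.
    """
    nx, ny, nz = shape
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    aff[0, 3] = -voxel_size_mm * (nx - 1) / 2.0
    # y runs from -(ny-1)*vox + 2mm up to +2mm-ish: posterior negative
    aff[1, 3] = -voxel_size_mm * (ny - 2)
    aff[2, 3] = -voxel_size_mm * (nz - 1) / 2.0
    return aff


@dataclass
class VoxelGrid:
    """A 3-D array of values plus its voxel->mm affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_space(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def coords_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of voxel indices to mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def axis_coords_mm(self, axis: int) -> tuple[np.ndarray, int]:
        """World coordinate of every voxel centre along one world axis.

        Requires the affine to be axis-aligned for that world axis (a
        single voxel axis maps onto it); raises otherwise.
        """
        row = self.affine[axis, :3]
        nz = np.nonzero(np.abs(row) > 1e-9)[0]
        if len(nz) != 1:
            raise ValueError(
                f"affine has no single voxel axis for world axis {axis}; "
                "oblique affines are not supported for axis cuts"
            )
        vax = int(nz[0])
        idx = np.arange(self.shape[vax])
        coords = row[vax] * idx + self.affine[axis, 3]
        return coords, vax

    # -- NIfTI round trip -------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        return nib.Nifti1Image(data, self.affine)

    @classmethod
    def from_nifti(cls, img: nib.Nifti1Image) -> "VoxelGrid":
        return cls(np.asarray(img.dataobj), np.asarray(img.affine))

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        return cls.from_nifti(nib.load(str(path)))

    def with_data(self, data: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(data, self.affine.copy())
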