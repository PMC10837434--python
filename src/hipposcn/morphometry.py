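"""Gray-matter summary measures.

Seed mean densities, subregion volumes (mean density x voxel count,
summed over hemispheres), the cohort analysis mask (voxels whose mean
density across subjects exceeds a gray-matter cutoff), isotropic
Gaussian smoothing, and the subjects-by-voxels cohort matrix consumed
by the PLS stage.

Volumes are reported in density-weighted voxel units by default; the
study's convention (mean modulated density x voxel count per
hemisphere, left + right) is unit-free, and multiplying by the voxel
volume converts to density-weighted mm^3 when needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import VoxelGrid

__all__ = [
    "GMImage",
    "CohortMatrix",
    "mean_density",
    "subregion_volume",
    "build_analysis_mask",
    "smooth",
    "assemble_cohort_matrix",
    "disassemble_cohort_matrix",
    "volumes_table",
    "FWHM_TO_SIGMA",
]

# FWHM = 2 * sqrt(2 ln 2) * sigma for a Gaussian
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class GMImage:
    """A modulated gray-matter density map for one subject."""

    grid: VoxelGrid
    subject_id: str = ""
    smoothed: bool = False

    def __post_init__(self) -> None:
        data = np.asarray(self.grid.data)
        if not np.all(np.isfinite(data)):
            raise ValueError("GM density values must be finite")
        if data.min() < 0:
            raise ValueError("GM density values must be non-negative")


@dataclass
class CohortMatrix:
    """Subjects x in-mask-voxels density matrix.

    ``voxel_index`` maps each column to its (i, j, k) grid coordinate;
    rows follow ``subject_order``.
    """

    values: np.ndarray
    voxel_index: np.ndarray  # (n_voxels, 3) int
    subject_order: list[str]
    affine: np.ndarray
    grid_shape: tuple[int, int, int]
    smoothed: bool = False

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.subject_order), len(self.voxel_index)):
            raise ValueError("values shape inconsistent with subjects/voxels")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def map_to_grid(self, column_values: np.ndarray, fill: float = 0.0) -> VoxelGrid:
        """Scatter a per-voxel vector (e.g. saliences, BSRs) back onto
        the 3-D lattice."""
        column_values = np.asarray(column_values, dtype=float)
        if column_values.shape != (self.n_voxels,):
            raise ValueError("one value per matrix column required")
        out = np.full(self.grid_shape, fill, dtype=float)
        out[tuple(self.voxel_index.T)] = column_values
        return VoxelGrid(out, self.affine)


def _as_bool(mask: VoxelGrid | np.ndarray) -> np.ndarray:
    data = mask.data if isinstance(mask, VoxelGrid) else mask
    return np.asarray(data).astype(bool)


def mean_density(img: GMImage, mask: VoxelGrid | np.ndarray) -> float:
    """Arithmetic mean of the image's density over the mask voxels."""
    m = _as_bool(mask)
    if m.shape != img.grid.shape:
        raise ValueError("mask shape does not match image")
    if not m.any():
        raise ValueError("mask is empty")
    return float(np.asarray(img.grid.data)[m].mean())


def subregion_volume(
    img: GMImage, left: VoxelGrid | np.ndarray, right: VoxelGrid | np.ndarray
) -> float:
    """Density-weighted subregion volume.

    Mean density within each hemisphere mask times that mask's voxel
    count, summed over hemispheres; algebraically the sum of in-mask
    densities, left + right.
    """
    total = 0.0
    for m in (left, right):
        b = _as_bool(m)
        if not b.any():
            raise ValueError("empty hemisphere mask")
        total += mean_density(img, b) * int(b.sum())
    return float(total)


def build_analysis_mask(imgs: list[GMImage], threshold: float = 0.1) -> VoxelGrid:
    """Binary analysis mask: voxels whose mean density across subjects
    exceeds ``threshold`` (strict), from the cohort-average GM template.
    """
    if len(imgs) < 2:
        raise ValueError("need at least 2 images")
    ref = imgs[0].grid
    mean_img = np.zeros(ref.shape, dtype=float)
    for im in imgs:
        if not ref.same_space(im.grid):
            raise ValueError("images must share shape and affine")
        mean_img += np.asarray(im.grid.data, dtype=float)
    mean_img /= len(imgs)
    kept = mean_img > threshold
    if not kept.any():
        raise ValueError(
            f"analysis mask is empty at threshold {threshold} "
            f"(global max mean density {mean_img.max():.4g})"
        )
    return ref.with_data(kept)


def smooth(img: GMImage, fwhm_mm: float, truncate: float = 6.0) -> GMImage:
    """Isotropic Gaussian smoothing with the given FWHM in mm.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted to voxels by
    the affine's voxel sizes.  Boundaries are handled by mirroring
    (half-sample symmetric), which conserves total mass.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigmas_vox = fwhm_mm * FWHM_TO_SIGMA / img.grid.voxel_sizes_mm
    data = ndimage.gaussian_filter(
        np.asarray(img.grid.data, dtype=float),
        sigma=sigmas_vox,
        mode="reflect",
        truncate=truncate,
    )
    # float round-off can push values a hair below zero
    np.clip(data, 0.0, None, out=data)
    return GMImage(img.grid.with_data(data), img.subject_id, smoothed=True)


def assemble_cohort_matrix(
    imgs: list[GMImage], mask: VoxelGrid | np.ndarray, smoothed: bool | None = None
) -> CohortMatrix:
    """Stack per-subject in-mask densities into a subjects x voxels
    matrix (column order = C-order scan of the mask)."""
    if not imgs:
        raise ValueError("no images")
    m = _as_bool(mask)
    ref = imgs[0].grid
    if m.shape != ref.shape:
        raise ValueError("mask shape does not match images")
    voxel_index = np.argwhere(m)
    rows = []
    for im in imgs:
        if not ref.same_space(im.grid):
            raise ValueError("images must share shape and affine")
        rows.append(np.asarray(im.grid.data, dtype=float)[m])
    if smoothed is None:
        smoothed = all(im.smoothed for im in imgs)
    return CohortMatrix(
        values=np.vstack(rows),
        voxel_index=voxel_index,
        subject_order=[im.subject_id for im in imgs],
        affine=ref.affine.copy(),
        grid_shape=ref.shape,
        smoothed=bool(smoothed),
    )


def disassemble_cohort_matrix(cm: CohortMatrix) -> list[VoxelGrid]:
    """Inverse of :func:`assemble_cohort_matrix` (zeros off-mask)."""
    return [cm.map_to_grid(cm.values[i]) for i in range(cm.n_subjects)]


def volumes_table(
    imgs: list[GMImage],
    anterior_left: VoxelGrid,
    anterior_right: VoxelGrid,
    posterior_left: VoxelGrid,
    posterior_right: VoxelGrid,
) -> pd.DataFrame:
    """Per-subject aHPC/pHPC volumes and bilateral seed mean densities."""
    ant = _as_bool(anterior_left.data) | _as_bool(anterior_right.data)
    post = _as_bool(posterior_left.data) | _as_bool(posterior_right.data)
    rows = []
    for im in imgs:
        rows.append({
            "subject_id": im.subject_id,
            "aHPC_volume": subregion_volume(im, anterior_left, anterior_right),
            "pHPC_volume": subregion_volume(im, posterior_left, posterior_right),
            "aHPC_mean_density": mean_density(im, ant),
            "pHPC_mean_density": mean_density(im, post),
        })
    return pd.DataFrame(rows)
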