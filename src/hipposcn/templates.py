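"""Probabilistic anterior/posterior hippocampus templates.

Per-subject hippocampal subfield label maps (head / body / tail) are
aggregated into anterior (head) and posterior (body + tail) masks,
merged across subjects into probabilistic templates (each voxel's value
is the fraction of subjects whose mask contains it), thresholded at a
retention probability (default 0.75: a voxel is kept iff present in at
least 75% of the sample), and finally cut along the longitudinal (y)
axis to drop the functionally mixed middle portion of the hippocampus:
the posterior template keeps y <= -32 mm, the anterior keeps
y >= -21 mm.  Both cut comparisons are inclusive so the printed
criterion coordinates are themselves retained.

Voxel membership under the cuts is decided by the voxel-centre
coordinate.  Thresholding uses ``>=`` throughout and is idempotent.
The cut commutes with thresholding (it is a per-voxel restriction), so
applying it after thresholding is equivalent to applying it to every
subject mask first.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grids import VoxelGrid
from .synthgen import LABEL_BODY, LABEL_HEAD, LABEL_TAIL, VALID_LABELS

__all__ = [
    "TemplateConfig",
    "ProbabilisticTemplate",
    "aggregate_subfields",
    "build_probabilistic_template",
    "threshold_template",
    "apply_axis_cuts",
    "split_hemispheres",
    "build_region_templates",
]


@dataclass
class TemplateConfig:
    """Threshold and longitudinal-axis cut settings (mm, MNI y axis)."""

    prob_threshold: float = 0.75
    posterior_cut_mm: float = -32.0
    anterior_cut_mm: float = -21.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prob_threshold <= 1.0:
            raise ValueError("prob_threshold must lie in (0, 1]")
        if not self.posterior_cut_mm < self.anterior_cut_mm:
            raise ValueError("posterior_cut_mm must be < anterior_cut_mm")


@dataclass
class ProbabilisticTemplate:
    """Voxelwise fraction of subjects whose mask contains each voxel.

    Values are exact rationals k / n_subjects stored as floats.
    """

    grid: VoxelGrid
    n_subjects: int
    region_name: str = ""

    def __post_init__(self) -> None:
        vals = self.grid.data
        if vals.min() < 0 or vals.max() > 1:
            raise ValueError("template values must lie in [0, 1]")

    def to_sidecar(self, cfg: TemplateConfig | None = None) -> dict:
        meta = {"n_subjects": self.n_subjects, "region_name": self.region_name}
        if cfg is not None:
            meta.update(
                prob_threshold=cfg.prob_threshold,
                posterior_cut_mm=cfg.posterior_cut_mm,
                anterior_cut_mm=cfg.anterior_cut_mm,
            )
        return meta

    def save(self, path: str | Path, cfg: TemplateConfig | None = None) -> None:
        path = Path(path)
        self.grid.save(path)
        sidecar = path.with_name(path.name.split(".")[0] + ".json")
        sidecar.write_text(json.dumps(self.to_sidecar(cfg), indent=2))


def aggregate_subfields(labels: VoxelGrid) -> tuple[VoxelGrid, VoxelGrid]:
    """Split a subfield label map into anterior (head) and posterior
    (body + tail) binary masks.  The masks are disjoint by construction.
    """
    arr = np.asarray(labels.data)
    codes = set(np.unique(arr).tolist())
    if not codes <= VALID_LABELS:
        raise ValueError(
            f"unknown label codes {sorted(codes - VALID_LABELS)}; "
            "expected {0: background, 1: head, 2: body, 3: tail}"
        )
    anterior = labels.with_data(arr == LABEL_HEAD)
    posterior = labels.with_data((arr == LABEL_BODY) | (arr == LABEL_TAIL))
    return anterior, posterior


def build_probabilistic_template(
    masks: list[VoxelGrid], region_name: str = ""
) -> ProbabilisticTemplate:
    """Merge binary masks across subjects into a probabilistic template."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks to build a template")
    ref = masks[0]
    for m in masks[1:]:
        if not ref.same_space(m):
            raise ValueError("all masks must share shape and affine")
    counts = np.zeros(ref.shape, dtype=np.int64)
    for m in masks:
        counts += np.asarray(m.data).astype(bool)
    grid = ref.with_data(counts / float(len(masks)))
    return ProbabilisticTemplate(grid, n_subjects=len(masks),
                                 region_name=region_name)


def threshold_template(t: ProbabilisticTemplate, p: float) -> VoxelGrid:
    """Voxels present in at least a fraction ``p`` of subjects (inclusive).

    An empty result is legal (warned about, not an error): with few
    subjects and heavy boundary disagreement no voxel may survive.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    # counts are exact integers; compare k >= ceil(p * n) to avoid
    # float-quantisation surprises at exact fractions like 0.75 * n
    n = t.n_subjects
    k = np.rint(np.asarray(t.grid.data) * n).astype(np.int64)
    kept = k >= int(np.ceil(p * n - 1e-9))
    if not kept.any():
        warnings.warn(
            f"threshold {p} leaves an empty {t.region_name or 'template'} mask",
            stacklevel=2,
        )
    return t.grid.with_data(kept)


def apply_axis_cuts(
    anterior: VoxelGrid, posterior: VoxelGrid, cfg: TemplateConfig
) -> tuple[VoxelGrid, VoxelGrid]:
    """Longitudinal-axis cuts: posterior keeps voxel centres at
    y <= posterior_cut_mm, anterior keeps y >= anterior_cut_mm; the
    middle band belongs to neither."""
    ycoords_a, vax_a = anterior.axis_coords_mm(1)
    ycoords_p, vax_p = posterior.axis_coords_mm(1)

    def cut(grid: VoxelGrid, ycoords, vax, keep_mask_1d) -> VoxelGrid:
        data = np.asarray(grid.data).astype(bool).copy()
        sel = [slice(None)] * 3
        drop = ~keep_mask_1d
        idx = np.nonzero(drop)[0]
        for i in idx:
            sel[vax] = i
            data[tuple(sel)] = False
        return grid.with_data(data)

    ant = cut(anterior, ycoords_a, vax_a, ycoords_a >= cfg.anterior_cut_mm)
    post = cut(posterior, ycoords_p, vax_p, ycoords_p <= cfg.posterior_cut_mm)
    return ant, post


def split_hemispheres(mask: VoxelGrid) -> tuple[VoxelGrid, VoxelGrid]:
    """Split a bilateral mask into (left, right) by the sign of the
    voxel-centre x coordinate (left = x < 0, RAS+ convention)."""
    xcoords, vax = mask.axis_coords_mm(0)
    data = np.asarray(mask.data).astype(bool)
    left = np.zeros_like(data)
    right = np.zeros_like(data)
    sel = [slice(None)] * 3
    for i, x in enumerate(xcoords):
        sel[vax] = i
        if x < 0:
            left[tuple(sel)] = data[tuple(sel)]
        else:
            right[tuple(sel)] = data[tuple(sel)]
    return mask.with_data(left), mask.with_data(right)


def build_region_templates(
    subject_labels: list[VoxelGrid], cfg: TemplateConfig | None = None
) -> dict:
    """Full template stage: aggregate each subject's subfields, merge
    into probabilistic anterior/posterior templates, threshold, cut.

    Returns a dict with the probabilistic templates, the final binary
    masks and their hemisphere splits.
    """
    cfg = cfg or TemplateConfig()
    ant_masks, post_masks = [], []
    for labels in subject_labels:
        a, p = aggregate_subfields(labels)
        ant_masks.append(a)
        post_masks.append(p)
    ant_t = build_probabilistic_template(ant_masks, "aHPC")
    post_t = build_probabilistic_template(post_masks, "pHPC")
    ant_bin = threshold_template(ant_t, cfg.prob_threshold)
    post_bin = threshold_template(post_t, cfg.prob_threshold)
    ant_bin, post_bin = apply_axis_cuts(ant_bin, post_bin, cfg)
    ant_l, ant_r = split_hemispheres(ant_bin)
    post_l, post_r = split_hemispheres(post_bin)
    return {
        "anterior_prob": ant_t,
        "posterior_prob": post_t,
        "anterior": ant_bin,
        "posterior": post_bin,
        "anterior_left": ant_l,
        "anterior_right": ant_r,
        "posterior_left": post_l,
        "posterior_right": post_r,
        "config": cfg,
    }
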