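"""Synthetic cohorts with planted ground truth.

Emulates the inputs of a hippocampal structural-covariance study:
modulated gray-matter density maps, per-subject hippocampus subfield
label masks, a covariate table and long-format EMA survey records of
trauma-related intrusive-memory (TR-IM) counts.

The generative model is deliberately simple so every downstream stage
has a recoverable truth:

* a standard-normal latent factor ``f_i`` per subject drives both the
  anterior-hippocampus seed voxels and a designated set of "network"
  voxels (loading ``latent_loading_seed`` / ``latent_loading_network``);
* an independent factor ``g_i`` drives the posterior-seed voxels;
* every other voxel is pure Gaussian noise; densities are clipped at 0
  (a mild truncation — the baseline sits several noise SDs above 0 in
  the signal regions, so clipping is effectively confined to
  background);
* TR-IM counts are Poisson with log rate ``beta0 + beta_brain * z(f)``
  per day, the day's exposure shared equally across its three TR-IM
  survey slots.

The geometry mirrors the MNI convention: the grid's second axis is the
anterior-posterior (y) axis with posterior more negative, so that the
longitudinal-axis template cuts (y = -32 / y = -21 mm) are exercised
realistically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from math import log
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import VoxelGrid, default_affine

__all__ = [
    "SynthConfig",
    "SynthCohort",
    "generate_cohort",
    "generate_subject_masks",
    "plant_counts",
    "write_cohort",
    "TRIM_SLOTS",
    "N_DAYS",
    "N_SLOTS_PER_DAY",
]

# EMA schedule: 5 daily surveys for 14 days; slots 2-4 probe TR-IMs
# (3 x 14 = 42 TR-IM surveys, 70 surveys total).
N_DAYS = 14
N_SLOTS_PER_DAY = 5
TRIM_SLOTS = (2, 3, 4)

LABEL_BACKGROUND, LABEL_HEAD, LABEL_BODY, LABEL_TAIL = 0, 1, 2, 3


def subject_ids(n: int) -> list[str]:
    """Zero-padded ids whose lexicographic order equals numeric order."""
    width = max(3, len(str(n)))
    return [f"s{i + 1:0{width}d}" for i in range(n)]
VALID_LABELS = frozenset({LABEL_BACKGROUND, LABEL_HEAD, LABEL_BODY, LABEL_TAIL})


@dataclass
class SynthConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the scale of the study being emulated: 93
    subjects, ~80% female, a baseline TR-IM rate of 1.5/day over 14
    days (expected total ~21), ~84% survey completion, and a negative
    log-IRR of the latent brain factor on the count rate.
    """

    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: float = 2.0
    n_subjects: int = 93
    baseline: float = 4.0
    latent_loading_seed: float = 0.6
    latent_loading_network: float = 0.6
    noise_sd: float = 0.8
    mask_jitter_prob: float = 0.1
    beta0: float = log(1.5)
    beta_brain: float = -0.105
    completion_prob: float = 0.84
    rng_seed: int = 0

    def validate(self) -> None:
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError("grid_shape must be three positive integers")
        if any(s < 8 for s in shape):
            raise ValueError(
                "grid too small: every dimension must be >= 8 voxels to host "
                "disjoint anterior/posterior/network regions"
            )
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("mask_jitter_prob", "completion_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass
class SynthCohort:
    """A generated cohort: images, masks, truth, tables."""

    gm_images: list[VoxelGrid]
    subject_masks: list[VoxelGrid]
    truth: dict
    subjects: pd.DataFrame
    ema: pd.DataFrame
    config: SynthConfig = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects["subject_id"])


# ---------------------------------------------------------------------------
# Geometry


def _region_slices(shape: tuple[int, int, int], affine: np.ndarray) -> dict:
    """Place bilateral head/body/tail blobs and a cortical "network"
    region on the lattice, scaled to the grid size.

    Regions are boxes; the head sits anterior of y = -21 mm, the tail
    posterior of y = -32 mm and the body in between, so the axis cuts
    remove exactly the body ("middle portion").
    """
    nx, ny, nz = shape
    ycoords = affine[1, 1] * np.arange(ny) + affine[1, 3]

    def j_range(lo_mm, hi_mm):
        js = np.nonzero((ycoords >= lo_mm) & (ycoords <= hi_mm))[0]
        if len(js) == 0:
            raise ValueError(
                f"grid y extent does not cover [{lo_mm}, {hi_mm}] mm; "
                "the lattice must span roughly -44..-8 mm along y "
                "(increase ny or voxel_size_mm)"
            )
        return int(js[0]), int(js[-1]) + 1

    j_head = j_range(-20.5, -8.0)
    j_body = j_range(-30.5, -23.5)
    j_tail = j_range(-44.0, -33.5)

    # hemisphere x bands, inner part of each half
    xl = (max(1, nx // 5), max(2, nx // 2 - 1))
    xr = (nx - xl[1], nx - xl[0])
    kz = (max(1, nz // 2 - 2), min(nz - 1, nz // 2 + 2))  # mid-axial band

    # large superior "cortical" network blobs
    k_net = (min(nz - 4, nz // 2 + 3), nz - 1)
    x_net_l = (1, nx // 2 - 1)
    x_net_r = (nx // 2 + 1, nx - 1)
    j_net = (ny // 3, ny - 1)

    return {
        "head": [(slice(*xl), slice(*j_head), slice(*kz)),
                 (slice(*xr), slice(*j_head), slice(*kz))],
        "body": [(slice(*xl), slice(*j_body), slice(*kz)),
                 (slice(*xr), slice(*j_body), slice(*kz))],
        "tail": [(slice(*xl), slice(*j_tail), slice(*kz)),
                 (slice(*xr), slice(*j_tail), slice(*kz))],
        "network": [(slice(*x_net_l), slice(*j_net), slice(*k_net)),
                    (slice(*x_net_r), slice(*j_net), slice(*k_net))],
    }


def make_truth_regions(config: SynthConfig) -> tuple[VoxelGrid, np.ndarray]:
    """Truth label grid (0/1/2/3 = background/head/body/tail) and the
    boolean network mask, on the configured lattice."""
    shape = tuple(int(s) for s in config.grid_shape)
    affine = default_affine(shape, config.voxel_size_mm)
    regions = _region_slices(shape, affine)

    labels = np.zeros(shape, dtype=np.int16)
    network = np.zeros(shape, dtype=bool)
    for sl in regions["network"]:
        network[sl] = True
    for name, code in (("head", LABEL_HEAD), ("body", LABEL_BODY),
                       ("tail", LABEL_TAIL)):
        for sl in regions[name]:
            labels[sl] = code
    network &= labels == 0  # hippocampal labels take precedence
    return VoxelGrid(labels, affine), network


# ---------------------------------------------------------------------------
# Mask jitter


def generate_subject_masks(
    truth_labels: VoxelGrid | np.ndarray,
    jitter: float,
    n_subjects: int,
    rng_seed: int,
) -> list[VoxelGrid]:
    """Per-subject label masks: truth with noisy region boundaries.

    With probability ``jitter`` a boundary voxel's membership is
    re-randomized (kept or flipped with equal chance); interior voxels
    are stable.  At ``jitter = 1`` boundary membership is a fair coin,
    so probabilistic-template values at the boundary converge to 0.5.
    Boundary voxels are region voxels with a 6-neighbour background
    voxel and background voxels with a 6-neighbour region voxel.
    """
    if not 0.0 <= jitter <= 1.0:
        raise ValueError(f"jitter must lie in [0, 1], got {jitter}")
    if isinstance(truth_labels, VoxelGrid):
        labels, affine = truth_labels.data, truth_labels.affine
    else:
        labels, affine = np.asarray(truth_labels), np.eye(4)
    labels = labels.astype(np.int16)
    if not set(np.unique(labels)) <= VALID_LABELS:
        raise ValueError(
            f"unknown label codes {sorted(set(np.unique(labels)) - VALID_LABELS)}; "
            "expected {0, 1, 2, 3}"
        )

    region = labels > 0
    pad = np.pad(region, 1)
    has_bg_neighbour = np.zeros_like(region)
    has_region_neighbour = np.zeros_like(region)
    shifts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for dx, dy, dz in shifts:
        nb = pad[1 + dx:pad.shape[0] - 1 + dx,
                 1 + dy:pad.shape[1] - 1 + dy,
                 1 + dz:pad.shape[2] - 1 + dz]
        has_bg_neighbour |= ~nb
        has_region_neighbour |= nb

    out_boundary = region & has_bg_neighbour          # may leave the region
    in_boundary = (~region) & has_region_neighbour    # may join it
    in_idx = np.argwhere(in_boundary)

    # code a joining background voxel takes: nearest region neighbour's
    # label, first found in a fixed shift order (deterministic)
    padl = np.pad(labels, 1)
    join_code = np.zeros(len(in_idx), dtype=np.int16)
    for s, (dx, dy, dz) in enumerate(shifts):
        nb = padl[1 + dx:padl.shape[0] - 1 + dx,
                  1 + dy:padl.shape[1] - 1 + dy,
                  1 + dz:padl.shape[2] - 1 + dz]
        vals = nb[tuple(in_idx.T)]
        take = (join_code == 0) & (vals > 0)
        join_code[take] = vals[take]

    out_idx = np.argwhere(out_boundary)
    rng = np.random.default_rng(rng_seed)
    masks: list[VoxelGrid] = []
    for _ in range(n_subjects):
        m = labels.copy()
        if len(out_idx):
            resample = rng.random(len(out_idx)) < jitter
            drop = resample & (rng.random(len(out_idx)) < 0.5)
            m[tuple(out_idx[drop].T)] = LABEL_BACKGROUND
        if len(in_idx):
            resample = rng.random(len(in_idx)) < jitter
            add = resample & (rng.random(len(in_idx)) < 0.5)
            m[tuple(in_idx[add].T)] = join_code[add]
        masks.append(VoxelGrid(m, affine))
    return masks


# ---------------------------------------------------------------------------
# EMA counts


def plant_counts(true_scores: np.ndarray, config: SynthConfig,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Long-format EMA records with Poisson TR-IM counts.

    Schedule: 14 days x 5 slots; slots 2-4 are TR-IM surveys.  Each
    slot is completed with ``completion_prob``.  A completed TR-IM
    slot's count is Poisson with daily log rate
    ``beta0 + beta_brain * z(true_score)``, the day's exposure split
    equally across the three TR-IM slots.
    """
    config.validate()
    scores = np.asarray(true_scores, dtype=float)
    n = len(scores)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    sd = scores.std(ddof=0)
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros(n)
    daily_rate = np.exp(config.beta0 + config.beta_brain * z)

    rows = []
    ids = subject_ids(n)
    for i in range(n):
        sid = ids[i]
        for day in range(1, N_DAYS + 1):
            for slot in range(1, N_SLOTS_PER_DAY + 1):
                completed = bool(rng.random() < config.completion_prob)
                count: float | int = np.nan
                if completed and slot in TRIM_SLOTS:
                    count = int(rng.poisson(daily_rate[i] / len(TRIM_SLOTS)))
                rows.append((sid, day, slot, completed, count))
    return pd.DataFrame(
        rows, columns=["subject_id", "day", "slot", "completed", "trim_count"]
    )


# ---------------------------------------------------------------------------
# Cohort


def generate_cohort(config: SynthConfig) -> SynthCohort:
    """Generate a full synthetic cohort (images, masks, tables, truth).

    Deterministic: identical configs (including ``rng_seed``) yield
    byte-identical cohorts.
    """
    config.validate()
    truth_grid, network = make_truth_regions(config)
    labels = truth_grid.data
    affine = truth_grid.affine
    shape = labels.shape
    n = config.n_subjects

    ss = np.random.SeedSequence(config.rng_seed)
    s_factors, s_noise, s_masks, s_cov, s_ema = ss.spawn(5)
    rng_f = np.random.default_rng(s_factors)
    rng_n = np.random.default_rng(s_noise)
    rng_c = np.random.default_rng(s_cov)

    f = rng_f.standard_normal(n)   # anterior/network latent factor
    g = rng_f.standard_normal(n)   # independent posterior factor

    anterior_seed = labels == LABEL_HEAD
    posterior_seed = (labels == LABEL_BODY) | (labels == LABEL_TAIL)

    base = np.zeros(shape)
    base[anterior_seed | posterior_seed | network] = config.baseline

    gm_images: list[VoxelGrid] = []
    for i in range(n):
        img = base.copy()
        img[anterior_seed] += config.latent_loading_seed * f[i]
        img[network] += config.latent_loading_network * f[i]
        img[posterior_seed] += config.latent_loading_seed * g[i]
        img += rng_n.normal(0.0, config.noise_sd, size=shape)
        np.clip(img, 0.0, None, out=img)
        gm_images.append(VoxelGrid(img, affine))

    masks = generate_subject_masks(
        truth_grid, config.mask_jitter_prob, n,
        int(s_masks.generate_state(1)[0] % (2**31)),
    )

    ids = subject_ids(n)
    age = np.clip(np.round(rng_c.normal(33.0, 11.0, n)), 18, 65)
    sex = (rng_c.random(n) < 0.8).astype(int)  # 1 = female (~80%)
    caps = np.clip(np.round(rng_c.normal(24.4, 9.3, n)), 0, None).astype(int)

    ema = plant_counts(f, config, rng=np.random.default_rng(s_ema))

    subjects = pd.DataFrame({
        "subject_id": ids,
        "age": age,
        "sex": sex,
        "caps_composite": caps,
    })

    truth = {
        "latent_f": f.tolist(),
        "latent_g": g.tolist(),
        "true_brain_score": ((f - f.mean()) / f.std(ddof=0)).tolist(),
        "n_anterior_seed_voxels": int(anterior_seed.sum()),
        "n_posterior_seed_voxels": int(posterior_seed.sum()),
        "n_network_voxels": int(network.sum()),
        "config": asdict(config),
    }
    truth["_regions"] = {
        "labels": labels,
        "network": network,
        "anterior_seed": anterior_seed,
        "posterior_seed": posterior_seed,
        "truth_grid": truth_grid,
    }
    return SynthCohort(gm_images, masks, truth, subjects, ema, config)


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> None:
    """Serialize a cohort: NIfTI images/masks, CSV tables, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sid, img, mask in zip(cohort.subject_ids, cohort.gm_images,
                              cohort.subject_masks):
        img.save(outdir / f"gm_{sid}.nii.gz")
        mask.save(outdir / f"mask_{sid}.nii.gz")
    cohort.subjects.to_csv(outdir / "subjects.csv", index=False)
    cohort.ema.to_csv(outdir / "ema.csv", index=False)
    truth = {k: v for k, v in cohort.truth.items() if not k.startswith("_")}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
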