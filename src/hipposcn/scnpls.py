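"""Seed-based non-rotated partial least squares for structural covariance.

The structural covariance network (SCN) analysis relates the mean
gray-matter density of two seed regions (bilateral anterior and
posterior hippocampus) to every voxel of the brain across subjects:

1. a 2 x voxels seed-voxel association matrix (Pearson correlation by
   default, covariance optionally) is computed between the seed means
   and all in-mask voxels;
2. an a priori contrast over the seeds (default [+1, -1]/sqrt(2):
   anterior vs posterior) projects this matrix onto a single latent
   variable — its voxel saliences are ``contrast^T A`` and its singular
   value is the Euclidean norm of the saliences.  No SVD rotation is
   involved: the contrast, not the data, defines the latent variable;
3. significance of the latent variable comes from permutation of the
   seed table's subject rows (resampling without replacement);
4. voxelwise reliability comes from bootstrap resampling of subjects
   with replacement: the bootstrap ratio (BSR) is each voxel's salience
   divided by its bootstrap standard error, with |BSR| >= 3.3
   (two-tailed p ~ 0.001) conventionally taken as reliable;
5. each subject's brain score is the dot product of their (smoothed)
   GM image with the salience map;
6. suprathreshold BSR clusters are extracted per sign with a minimum
   size (default 100 voxels).

:class:`SeedPLS` packages steps 1-5 as a scikit-learn style estimator
(``fit`` on the unsmoothed cohort matrix + seed table, ``transform`` on
the smoothed cohort matrix for brain scores); module-level functions
expose each step individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .grids import VoxelGrid
from .morphometry import CohortMatrix

__all__ = [
    "SeedDensityTable",
    "LatentVariable",
    "ClusterRecord",
    "SeedPLS",
    "seed_voxel_association",
    "nonrotated_pls",
    "permutation_test",
    "bootstrap_bsr",
    "brain_scores",
    "extract_clusters",
    "DEFAULT_CONTRAST",
    "DEFAULT_BSR_THRESHOLD",
    "DEFAULT_MIN_CLUSTER",
]

DEFAULT_CONTRAST = (1.0, -1.0)
DEFAULT_BSR_THRESHOLD = 3.3   # two-tailed p ~ 0.001
DEFAULT_MIN_CLUSTER = 100     # voxels

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class SeedDensityTable:
    """Per-subject mean unsmoothed densities of the two seeds."""

    values: np.ndarray  # (n_subjects, 2)
    subject_order: list[str] = field(default_factory=list)
    seed_names: tuple[str, str] = ("aHPC", "pHPC")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("seed table must have exactly two seed columns")

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   columns: tuple[str, str] = ("aHPC_mean_density",
                                               "pHPC_mean_density")) -> "SeedDensityTable":
        return cls(df[list(columns)].to_numpy(dtype=float),
                   subject_order=list(df.get("subject_id", [])))


@dataclass
class LatentVariable:
    """A contrast-defined latent variable with its inference results."""

    contrast: np.ndarray
    saliences: np.ndarray
    singular_value: float
    perm_p: float | None = None
    boot_se: np.ndarray | None = None
    bsr: np.ndarray | None = None
    brain_scores: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0
    rng_seed: int | None = None
    zero_variance_voxels: np.ndarray | None = None


@dataclass
class ClusterRecord:
    """A suprathreshold BSR cluster."""

    peak_mm: tuple[float, float, float]
    size_voxels: int
    peak_bsr: float
    sign: str  # "positive" | "negative"
    peak_ijk: tuple[int, int, int] = (0, 0, 0)


# ---------------------------------------------------------------------------
# Core linear algebra


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, CohortMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _seed_values(seeds) -> np.ndarray:
    if isinstance(seeds, SeedDensityTable):
        return seeds.values
    return np.asarray(seeds, dtype=float)


def _association(X: np.ndarray, S: np.ndarray, method: str) -> tuple[np.ndarray, np.ndarray]:
    """2 x voxels association of seed columns S (n x 2) with voxel
    columns X (n x V); returns (assoc, zero_variance_voxel_mask).

    Zero-variance voxels get association 0; a zero-variance seed is an
    error for correlation (undefined for the quantity of interest).
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Sc = S - S.mean(axis=0)
    if method == "covariance":
        return (Sc.T @ Xc) / (n - 1), np.zeros(X.shape[1], dtype=bool)
    if method != "correlation":
        raise ValueError("method must be 'correlation' or 'covariance'")
    s_sd = Sc.std(axis=0, ddof=1)
    if np.any(s_sd == 0):
        raise ValueError("zero-variance seed column: correlation undefined")
    x_sd = Xc.std(axis=0, ddof=1)
    zero_var = x_sd == 0
    safe_sd = np.where(zero_var, 1.0, x_sd)
    assoc = (Sc / s_sd).T @ (Xc / safe_sd) / (n - 1)
    assoc[:, zero_var] = 0.0
    return assoc, zero_var


def _normalize_contrast(contrast) -> np.ndarray:
    c = np.asarray(contrast, dtype=float).ravel()
    if c.shape != (2,):
        raise ValueError("contrast must have two entries (one per seed)")
    norm = np.linalg.norm(c)
    if norm == 0:
        raise ValueError("contrast must be nonzero")
    return c / norm


def seed_voxel_association(
    cohort, seeds, method: str = "correlation", return_flags: bool = False
):
    """Between-subject association of each seed's mean density with
    every voxel (rows: seeds; columns: voxels)."""
    X = _as_matrix(cohort)
    S = _seed_values(seeds)
    if X.shape[0] != S.shape[0]:
        raise ValueError("cohort and seed table have different subject counts")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    assoc, zero_var = _association(X, S, method)
    return (assoc, zero_var) if return_flags else assoc


def nonrotated_pls(assoc: np.ndarray, contrast) -> tuple[np.ndarray, float]:
    """Project the association matrix onto a unit-normalized a priori
    contrast: saliences = contrast^T A, singular value = ||saliences||.
    Positive saliences mark voxels covarying with the positively
    weighted seed."""
    c = _normalize_contrast(contrast)
    assoc = np.asarray(assoc, dtype=float)
    if assoc.shape[0] != 2:
        raise ValueError("association matrix must have 2 rows")
    saliences = c @ assoc
    return saliences, float(np.linalg.norm(saliences))


def brain_scores(smoothed_cohort, saliences: np.ndarray) -> np.ndarray:
    """Per-subject expression of the pattern: dot product of each
    subject's (smoothed) GM densities with the voxel saliences."""
    if isinstance(smoothed_cohort, CohortMatrix) and not smoothed_cohort.smoothed:
        raise ValueError("brain scores are defined on the smoothed cohort matrix")
    X = _as_matrix(smoothed_cohort)
    s = np.asarray(saliences, dtype=float)
    if X.shape[1] != s.shape[0]:
        raise ValueError(
            f"voxel-index mismatch: cohort has {X.shape[1]} voxels, "
            f"salience map has {s.shape[0]}"
        )
    return X @ s


# ---------------------------------------------------------------------------
# Resampling inference


def permutation_test(
    cohort, seeds, contrast=DEFAULT_CONTRAST, n_perm: int = 1000,
    rng_seed: int | None = None, method: str = "correlation",
    convention: str = "proportion",
) -> float:
    """Permutation p-value for the latent variable's singular value.

    Subject rows of the seed table are permuted (sampling without
    replacement) relative to the voxel data; p is the plain proportion
    of permuted singular values >= the observed one (``convention=
    'proportion'``), or (count+1)/(n_perm+1) with ``'add_one'``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng_seed is None:
        raise ValueError("permutation_test requires an explicit rng_seed")
    if convention not in ("proportion", "add_one"):
        raise ValueError("convention must be 'proportion' or 'add_one'")
    X = _as_matrix(cohort)
    S = _seed_values(seeds)
    c = _normalize_contrast(contrast)
    assoc, _ = _association(X, S, method)
    observed = float(np.linalg.norm(c @ assoc))

    rng = np.random.default_rng(rng_seed)
    n = X.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        assoc_p, _ = _association(X, S[perm], method)
        sv = float(np.linalg.norm(c @ assoc_p))
        if sv >= observed:
            count += 1
    if convention == "add_one":
        return (count + 1) / (n_perm + 1)
    return count / n_perm


def bootstrap_bsr(
    cohort, seeds, contrast=DEFAULT_CONTRAST, n_boot: int = 1000,
    rng_seed: int | None = None, method: str = "correlation",
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap standard errors and bootstrap ratios of the saliences.

    Subjects are resampled with replacement; saliences are recomputed
    per replicate under the fixed a priori contrast (no per-replicate
    re-standardization or sign correction is needed because the
    contrast is fixed).  ``boot_se`` is the across-replicate standard
    deviation; ``bsr = salience / boot_se``.  Voxels with zero bootstrap
    SE get NaN BSR and must never be reported as reliable.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if rng_seed is None:
        raise ValueError("bootstrap_bsr requires an explicit rng_seed")
    X = _as_matrix(cohort)
    S = _seed_values(seeds)
    c = _normalize_contrast(contrast)
    assoc, _ = _association(X, S, method)
    saliences = c @ assoc

    rng = np.random.default_rng(rng_seed)
    n = X.shape[0]
    reps = np.empty((n_boot, X.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, Sb = X[idx], S[idx]
        if np.any(Sb.std(axis=0) == 0):  # degenerate resample: redraw
            idx = rng.integers(0, n, size=n)
            Xb, Sb = X[idx], S[idx]
        assoc_b, _ = _association(Xb, Sb, method)
        reps[b] = c @ assoc_b
    boot_se = reps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bsr = np.where(boot_se > 0, saliences / boot_se, np.nan)
    return boot_se, bsr


# ---------------------------------------------------------------------------
# Cluster extraction


def extract_clusters(
    bsr_map: VoxelGrid,
    threshold: float = DEFAULT_BSR_THRESHOLD,
    min_size: int = DEFAULT_MIN_CLUSTER,
    connectivity: int = 26,
) -> list[ClusterRecord]:
    """Connected components of supra-threshold BSR voxels, one pass per
    sign (positive and negative maps are thresholded separately, so
    touching blobs of opposite sign stay distinct clusters).  Peaks are
    reported in mm."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    data = np.asarray(bsr_map.data, dtype=float)

    records: list[ClusterRecord] = []
    for sign, mask in (("positive", data >= threshold),
                       ("negative", data <= -threshold)):
        labeled, n_comp = ndimage.label(mask, structure=structure)
        for comp in range(1, n_comp + 1):
            idx = np.argwhere(labeled == comp)
            if len(idx) < min_size:
                continue
            vals = data[tuple(idx.T)]
            peak_local = int(np.argmax(np.abs(vals)))
            peak_ijk = tuple(int(v) for v in idx[peak_local])
            peak_mm = tuple(float(v) for v in bsr_map.coords_mm(idx[peak_local])[0])
            records.append(ClusterRecord(
                peak_mm=peak_mm,
                size_voxels=int(len(idx)),
                peak_bsr=float(vals[peak_local]),
                sign=sign,
                peak_ijk=peak_ijk,
            ))
    records.sort(key=lambda r: -abs(r.peak_bsr))
    return records


# ---------------------------------------------------------------------------
# Estimator


class SeedPLS(TransformerMixin, BaseEstimator):
    """Seed-based non-rotated PLS as a scikit-learn estimator.

    ``fit(X, seeds)`` takes the unsmoothed subjects-x-voxels matrix and
    the two-column seed mean-density table, and computes the
    association matrix, the contrast-projected saliences and singular
    value, the permutation p-value (if ``n_perm > 0``) and voxelwise
    bootstrap SEs/BSRs (if ``n_boot > 0``).  ``transform(X_smoothed)``
    returns per-subject brain scores.

    Parameters
    ----------
    contrast : pair of floats
        A priori seed contrast, normalized internally to unit length.
        The default ``(1, -1)`` opposes the anterior and posterior
        seeds; positive saliences then mark voxels covarying with the
        anterior seed.
    method : {"correlation", "covariance"}
        Seed-voxel association measure.
    n_perm, n_boot : int
        Resampling sizes; 0 disables the corresponding inference.
    p_value_convention : {"proportion", "add_one"}
    random_state : int
        Seed for the resampling RNG; required whenever ``n_perm > 0``
        or ``n_boot > 0`` (all stochastic operations take an explicit
        seed — there is no hidden global RNG state).
    """

    def __init__(
        self,
        contrast: tuple[float, float] = DEFAULT_CONTRAST,
        method: str = "correlation",
        n_perm: int = 1000,
        n_boot: int = 1000,
        p_value_convention: str = "proportion",
        random_state: int | None = None,
    ) -> None:
        self.contrast = contrast
        self.method = method
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.p_value_convention = p_value_convention
        self.random_state = random_state

    def fit(self, X, seeds):
        c = _normalize_contrast(self.contrast)
        if (self.n_perm > 0 or self.n_boot > 0) and self.random_state is None:
            raise ValueError(
                "random_state is required when permutation or bootstrap "
                "inference is enabled"
            )
        Xm = _as_matrix(X)
        S = _seed_values(seeds)
        assoc, zero_var = seed_voxel_association(
            Xm, S, method=self.method, return_flags=True
        )
        saliences, sv = nonrotated_pls(assoc, c)

        self.contrast_ = c
        self.assoc_ = assoc
        self.zero_variance_voxels_ = zero_var
        self.saliences_ = saliences
        self.singular_value_ = sv
        self.n_features_in_ = Xm.shape[1]

        ss = np.random.SeedSequence(self.random_state)
        s_perm, s_boot = ss.spawn(2)
        self.perm_p_ = None
        if self.n_perm > 0:
            self.perm_p_ = permutation_test(
                Xm, S, c, n_perm=self.n_perm,
                rng_seed=int(s_perm.generate_state(1)[0] % (2**31)),
                method=self.method, convention=self.p_value_convention,
            )
        self.boot_se_ = self.bsr_ = None
        if self.n_boot > 0:
            self.boot_se_, self.bsr_ = bootstrap_bsr(
                Xm, S, c, n_boot=self.n_boot,
                rng_seed=int(s_boot.generate_state(1)[0] % (2**31)),
                method=self.method,
            )
        return self

    def transform(self, X) -> np.ndarray:
        """Brain scores of the fitted pattern for each subject row."""
        check_is_fitted(self, "saliences_")
        return brain_scores(X, self.saliences_)

    def latent_variable(self, smoothed_cohort=None) -> LatentVariable:
        """Bundle the fitted results (optionally with brain scores)."""
        check_is_fitted(self, "saliences_")
        scores = None
        if smoothed_cohort is not None:
            scores = self.transform(smoothed_cohort)
        return LatentVariable(
            contrast=self.contrast_,
            saliences=self.saliences_,
            singular_value=self.singular_value_,
            perm_p=self.perm_p_,
            boot_se=self.boot_se_,
            bsr=self.bsr_,
            brain_scores=scores,
            n_perm=self.n_perm,
            n_boot=self.n_boot,
            rng_seed=self.random_state,
            zero_variance_voxels=self.zero_variance_voxels_,
        )
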