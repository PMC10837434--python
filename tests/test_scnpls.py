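"""Seed-based non-rotated PLS: association matrix, contrast projection,
permutation/bootstrap inference, brain scores, cluster extraction."""

from collections import deque
from itertools import product

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from hipposcn.grids import VoxelGrid, default_affine
from hipposcn.morphometry import CohortMatrix
from hipposcn.scnpls import (
    SeedDensityTable,
    SeedPLS,
    bootstrap_bsr,
    brain_scores,
    extract_clusters,
    nonrotated_pls,
    permutation_test,
    seed_voxel_association,
)

from conftest import seed_table_and_matrix

CONTRAST = (1.0, -1.0)


def _random_data(n=40, v=300, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, v))
    S = rng.random((n, 2))
    return X, S


class TestAssociation:
    def test_voxel_identical_to_seed_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        S = rng.random((30, 2))
        X = np.column_stack([S[:, 0], rng.random(30)])
        assoc = seed_voxel_association(X, S)
        assert assoc[0, 0] == pytest.approx(1.0)

    def test_independent_voxels_have_small_correlations(self):
        # sampling sd of a null correlation is ~1/sqrt(n); at n = 1000
        # the 0.1 bound sits at 3.2 sd, so 99%+ of voxels fall inside
        rng = np.random.default_rng(2)
        n = 1000
        S = rng.standard_normal((n, 2))
        X = rng.standard_normal((n, 400))
        assoc = seed_voxel_association(X, S)
        assert np.mean(np.abs(assoc) < 0.1) > 0.99

    def test_matches_scalar_correlation_loop_oracle(self):
        X, S = _random_data(seed=3)
        assoc = seed_voxel_association(X, S)
        for s in range(2):
            for v in range(0, X.shape[1], 17):
                r = stats.pearsonr(S[:, s], X[:, v]).statistic
                assert assoc[s, v] == pytest.approx(r, abs=1e-10)

    def test_covariance_method_matches_numpy(self):
        X, S = _random_data(seed=4)
        assoc = seed_voxel_association(X, S, method="covariance")
        for s in range(2):
            for v in range(0, X.shape[1], 23):
                cov = np.cov(S[:, s], X[:, v])[0, 1]
                assert assoc[s, v] == pytest.approx(cov, abs=1e-12)

    def test_zero_variance_voxel_flagged_and_zeroed(self):
        X, S = _random_data(n=20, v=5, seed=5)
        X[:, 2] = 1.0
        assoc, flags = seed_voxel_association(X, S, return_flags=True)
        assert flags[2] and not flags[0]
        assert np.all(assoc[:, 2] == 0.0)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            seed_voxel_association(np.ones((2, 4)), np.ones((2, 2)))


class TestNonrotatedPLS:
    def test_identical_rows_cancel_under_opposing_contrast(self):
        assoc = np.vstack([np.linspace(0, 1, 6)] * 2)
        sal, sv = nonrotated_pls(assoc, CONTRAST)
        np.testing.assert_allclose(sal, 0.0, atol=1e-15)
        assert sv == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assoc = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5]])
        sal, sv = nonrotated_pls(assoc, CONTRAST)
        np.testing.assert_allclose(
            sal, np.array([1.0, -1.0, 0.0]) / np.sqrt(2), atol=1e-12
        )
        assert sv == pytest.approx(1.0)

    def test_contrast_sign_flip_negates_saliences(self):
        X, S = _random_data(seed=6)
        assoc = seed_voxel_association(X, S)
        sal_a, sv_a = nonrotated_pls(assoc, (1, -1))
        sal_b, sv_b = nonrotated_pls(assoc, (-1, 1))
        np.testing.assert_allclose(sal_a, -sal_b, atol=1e-12)
        assert sv_a == pytest.approx(sv_b)

    def test_zero_contrast_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            nonrotated_pls(np.ones((2, 3)), (0, 0))

    def test_matches_bruteforce_oracle_on_random_cohort(self):
        """The full non-rotated PLS (correlation + contrast projection)
        agrees with an explicit per-voxel loop to 1e-10."""
        X, S = _random_data(n=50, v=2000, seed=7)
        assoc = seed_voxel_association(X, S)
        sal, sv = nonrotated_pls(assoc, CONTRAST)
        c = np.array(CONTRAST) / np.sqrt(2)
        expected = np.empty(X.shape[1])
        for v in range(X.shape[1]):
            r0 = stats.pearsonr(S[:, 0], X[:, v]).statistic
            r1 = stats.pearsonr(S[:, 1], X[:, v]).statistic
            expected[v] = c[0] * r0 + c[1] * r1
        np.testing.assert_allclose(sal, expected, atol=1e-10)
        assert sv == pytest.approx(np.linalg.norm(expected), abs=1e-10)


class TestPermutation:
    def test_perfect_signal_yields_zero_proportion_p(self):
        rng = np.random.default_rng(8)
        n = 100
        S = rng.standard_normal((n, 2))
        X = np.column_stack([S, rng.standard_normal((n, 50))])
        p = permutation_test(X, S, CONTRAST, n_perm=200, rng_seed=1)
        assert p < 0.05
        assert p == 0.0  # plain-proportion convention

    def test_add_one_convention_bounded_away_from_zero(self):
        rng = np.random.default_rng(9)
        n = 60
        S = rng.standard_normal((n, 2))
        X = np.column_stack([S, rng.standard_normal((n, 20))])
        p = permutation_test(X, S, CONTRAST, n_perm=99, rng_seed=1,
                             convention="add_one")
        assert p >= 1 / 100

    def test_invariant_to_joint_relabeling(self):
        """Jointly relabeling subjects leaves the observed statistic
        exactly unchanged and the Monte-Carlo p unchanged up to
        resampling error (the permutation distribution is identical;
        individual draws pair up differently)."""
        X, S = _random_data(n=30, v=80, seed=10)
        from hipposcn.scnpls import _association, _normalize_contrast

        c = _normalize_contrast(CONTRAST)
        sv = np.linalg.norm(c @ _association(X, S, "correlation")[0])
        perm = np.random.default_rng(0).permutation(30)
        sv_rel = np.linalg.norm(
            c @ _association(X[perm], S[perm], "correlation")[0]
        )
        assert sv_rel == pytest.approx(sv, abs=1e-12)

        p1 = permutation_test(X, S, CONTRAST, n_perm=1000, rng_seed=5)
        p2 = permutation_test(X[perm], S[perm], CONTRAST, n_perm=1000,
                              rng_seed=5)
        mc_sd = np.sqrt(2 * max(p1, 0.01) * (1 - max(p1, 0.01)) / 1000)
        assert abs(p1 - p2) <= 4 * mc_sd

    def test_requires_seed_and_valid_n_perm(self):
        X, S = _random_data(n=10, v=5)
        with pytest.raises(ValueError, match="rng_seed"):
            permutation_test(X, S, CONTRAST, n_perm=10)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(X, S, CONTRAST, n_perm=0, rng_seed=1)

    def test_planted_structure_detected_across_replicates(self, planted_cohort):
        """With planted loadings 0.6 at n = 100 the latent variable is
        significant (reduced n_perm = 200)."""
        S, X = seed_table_and_matrix(planted_cohort)
        p = permutation_test(X, S, CONTRAST, n_perm=200, rng_seed=3)
        assert p < 0.05


class TestBootstrap:
    def test_same_seed_reproducible(self):
        X, S = _random_data(n=30, v=60, seed=11)
        se1, bsr1 = bootstrap_bsr(X, S, CONTRAST, n_boot=50, rng_seed=4)
        se2, bsr2 = bootstrap_bsr(X, S, CONTRAST, n_boot=50, rng_seed=4)
        np.testing.assert_array_equal(se1, se2)
        np.testing.assert_array_equal(bsr1, bsr2)

    def test_planted_voxels_reliable_noise_voxels_not(self, planted_cohort):
        """Network voxels with population r ~ 0.6 at n = 100 exceed
        |BSR| = 3.3; almost no pure-noise voxel does."""
        S, X = seed_table_and_matrix(planted_cohort)
        reg = planted_cohort.truth["_regions"]
        flat_net = reg["network"].ravel()
        labels = reg["labels"].ravel()
        noise = ~flat_net & (labels == 0)
        _, bsr = bootstrap_bsr(X, S, CONTRAST, n_boot=200, rng_seed=6)
        net_bsr = bsr[flat_net]
        assert np.median(net_bsr) >= 3.3
        assert np.mean(np.abs(bsr[noise]) >= 3.3) < 0.01

    def test_zero_variance_voxel_gets_nan_bsr(self):
        X, S = _random_data(n=25, v=6, seed=12)
        X[:, 3] = 2.0  # constant voxel: salience 0 in every replicate
        _, bsr = bootstrap_bsr(X, S, CONTRAST, n_boot=30, rng_seed=7)
        assert np.isnan(bsr[3])

    def test_requires_seed_and_min_boot(self):
        X, S = _random_data(n=10, v=5)
        with pytest.raises(ValueError, match="rng_seed"):
            bootstrap_bsr(X, S, CONTRAST, n_boot=10)
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_bsr(X, S, CONTRAST, n_boot=1, rng_seed=1)


class TestBrainScores:
    def test_zero_saliences_give_zero_scores(self):
        X, _ = _random_data(n=12, v=30, seed=13)
        np.testing.assert_array_equal(brain_scores(X, np.zeros(30)), 0.0)

    def test_single_voxel_weight(self):
        X, _ = _random_data(n=12, v=30, seed=14)
        sal = np.zeros(30)
        sal[17] = 2.5
        np.testing.assert_allclose(brain_scores(X, sal), 2.5 * X[:, 17])

    def test_linearity_in_images(self):
        rng = np.random.default_rng(15)
        Xa, Xb = rng.random((10, 40)), rng.random((10, 40))
        sal = rng.standard_normal(40)
        lhs = brain_scores(2.0 * Xa + 0.5 * Xb, sal)
        rhs = 2.0 * brain_scores(Xa, sal) + 0.5 * brain_scores(Xb, sal)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_unsmoothed_cohort_matrix_rejected(self):
        cm = CohortMatrix(
            values=np.ones((3, 2)),
            voxel_index=np.array([[0, 0, 0], [0, 0, 1]]),
            subject_order=["a", "b", "c"],
            affine=np.eye(4),
            grid_shape=(2, 2, 2),
            smoothed=False,
        )
        with pytest.raises(ValueError, match="smoothed"):
            brain_scores(cm, np.ones(2))

    def test_voxel_mismatch_rejected(self):
        X, _ = _random_data(n=5, v=10)
        with pytest.raises(ValueError, match="mismatch"):
            brain_scores(X, np.ones(11))


def flood_fill_clusters(mask: np.ndarray, connectivity: int):
    """Independent BFS flood fill returning sorted voxel-index lists."""
    offsets = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if (connectivity == 6 and order == 1) or \
           (connectivity == 18 and order <= 2) or connectivity == 26:
            offsets.append(d)
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp, q = [], deque([start])
        seen[start] = True
        while q:
            cur = q.popleft()
            comp.append(cur)
            for d in offsets:
                nb = tuple(np.add(cur, d))
                if all(0 <= nb[i] < mask.shape[i] for i in range(3)) \
                        and mask[nb] and not seen[nb]:
                    seen[nb] = True
                    q.append(nb)
        comps.append(sorted(comp))
    return sorted(comps)


class TestClusters:
    def _map(self, arr, vox=2.0):
        return VoxelGrid(np.asarray(arr, float),
                         default_affine(np.shape(arr), vox))

    def test_min_size_drops_small_blob(self):
        arr = np.zeros((20, 20, 20))
        arr[1:7, 1:6, 1:6] = 5.0    # 150 voxels
        arr[10:14, 10:14, 10:15] = 5.0  # 80 voxels
        recs = extract_clusters(self._map(arr), 3.3, min_size=100)
        assert len(recs) == 1
        assert recs[0].size_voxels == 150
        assert recs[0].sign == "positive"

    def test_touching_opposite_signs_stay_separate(self):
        arr = np.zeros((12, 12, 12))
        arr[2:6, 2:8, 2:8] = 4.0
        arr[6:10, 2:8, 2:8] = -4.0
        recs = extract_clusters(self._map(arr), 3.3, min_size=10)
        assert sorted(r.sign for r in recs) == ["negative", "positive"]

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(16)
        arr = rng.standard_normal((14, 14, 14)) * 3
        recs = extract_clusters(self._map(arr), 3.3, min_size=1,
                                connectivity=connectivity)
        got_pos = sorted(r.size_voxels for r in recs if r.sign == "positive")
        got_neg = sorted(r.size_voxels for r in recs if r.sign == "negative")
        oracle_pos = sorted(len(c) for c in
                            flood_fill_clusters(arr >= 3.3, connectivity))
        oracle_neg = sorted(len(c) for c in
                            flood_fill_clusters(arr <= -3.3, connectivity))
        assert got_pos == oracle_pos
        assert got_neg == oracle_neg

    def test_peak_reported_in_mm(self):
        arr = np.zeros((10, 10, 10))
        arr[3:6, 3:6, 3:6] = 4.0
        arr[4, 4, 4] = 9.0
        grid = self._map(arr, vox=2.0)
        recs = extract_clusters(grid, 3.3, min_size=1)
        assert recs[0].peak_bsr == pytest.approx(9.0)
        expected_mm = grid.coords_mm(np.array([4, 4, 4]))[0]
        np.testing.assert_allclose(recs[0].peak_mm, expected_mm)

    def test_empty_map_gives_empty_list(self):
        recs = extract_clusters(self._map(np.zeros((8, 8, 8))), 3.3)
        assert recs == []


class TestSeedPLSEstimator:
    def test_fit_transform_matches_functions(self):
        X, S = _random_data(n=30, v=100, seed=17)
        est = SeedPLS(n_perm=50, n_boot=50, random_state=0).fit(X, S)
        assoc = seed_voxel_association(X, S)
        sal, sv = nonrotated_pls(assoc, CONTRAST)
        np.testing.assert_allclose(est.saliences_, sal)
        assert est.singular_value_ == pytest.approx(sv)
        np.testing.assert_allclose(est.transform(X), brain_scores(X, sal))

    def test_sklearn_clone_and_params(self):
        est = SeedPLS(n_perm=10, n_boot=10, random_state=1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_refit_same_state_is_deterministic(self):
        X, S = _random_data(n=25, v=60, seed=18)
        a = SeedPLS(n_perm=40, n_boot=40, random_state=9).fit(X, S)
        b = SeedPLS(n_perm=40, n_boot=40, random_state=9).fit(X, S)
        assert a.perm_p_ == b.perm_p_
        np.testing.assert_array_equal(a.bsr_, b.bsr_)

    def test_missing_random_state_rejected_when_stochastic(self):
        X, S = _random_data(n=10, v=5)
        with pytest.raises(ValueError, match="random_state"):
            SeedPLS(n_perm=10, n_boot=0).fit(X, S)
        est = SeedPLS(n_perm=0, n_boot=0).fit(X, S)  # deterministic: fine
        assert est.perm_p_ is None and est.bsr_ is None

    def test_seed_density_table_from_frame(self):
        import pandas as pd

        df = pd.DataFrame({
            "subject_id": ["a", "b", "c"],
            "aHPC_mean_density": [1.0, 2.0, 3.0],
            "pHPC_mean_density": [4.0, 5.0, 6.0],
        })
        t = SeedDensityTable.from_frame(df)
        np.testing.assert_array_equal(t.values[:, 0], [1, 2, 3])
        assert t.subject_order == ["a", "b", "c"]
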