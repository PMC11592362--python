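"""Mean-centered PLS core: centering, SVD, permutation and bootstrap inference."""

from itertools import combinations

import numpy as np
import pytest

from connscreen.mcpls import MeanCenteredPLS, cell_mean_center, pls_svd


def _two_group_data(rng, n_per_cell=5, n_features=6, effect=0.0):
    X = rng.standard_normal((2 * n_per_cell, n_features))
    X[:n_per_cell, 0] += effect
    cells = np.repeat([0, 1], n_per_cell)
    return X, cells


class TestCellMeanCenter:
    def test_identical_rows_center_to_zero(self):
        X = np.tile([1.0, 2.0, 3.0], (6, 1))
        M_c, grand = cell_mean_center(X, np.repeat([0, 1], 3), 2)
        np.testing.assert_allclose(M_c, 0.0)
        np.testing.assert_allclose(grand, [1.0, 2.0, 3.0])

    def test_two_cell_closed_form(self, rng):
        X, cells = _two_group_data(rng)
        M_c, _ = cell_mean_center(X, cells, 2)
        m1, m2 = X[cells == 0].mean(0), X[cells == 1].mean(0)
        np.testing.assert_allclose(M_c[0], (m1 - m2) / 2, atol=1e-12)
        np.testing.assert_allclose(M_c[1], -(m1 - m2) / 2, atol=1e-12)

    def test_column_sums_vanish_with_unbalanced_cells(self, rng):
        X = rng.standard_normal((16, 8))
        cells = np.array([0] * 3 + [1] * 5 + [2] * 2 + [3] * 6)
        M_c, _ = cell_mean_center(X, cells, 4)
        assert np.abs(M_c.sum(axis=0)).max() < 1e-12

    def test_empty_cell_rejected(self, rng):
        X = rng.standard_normal((4, 3))
        with pytest.raises(ValueError, match="empty"):
            cell_mean_center(X, np.array([0, 0, 1, 1]), 3)


class TestPlsSvd:
    def test_zero_matrix_degenerate(self):
        _, S, _, ev = pls_svd(np.zeros((4, 6)))
        np.testing.assert_allclose(S, 0.0)
        np.testing.assert_allclose(ev, 0.0)

    def test_two_cell_rank_one_closed_form(self, rng):
        X, cells = _two_group_data(rng, effect=2.0)
        M_c, _ = cell_mean_center(X, cells, 2)
        U, S, V, ev = pls_svd(M_c)
        m_diff = X[cells == 0].mean(0) - X[cells == 1].mean(0)
        assert S[0] == pytest.approx(np.linalg.norm(m_diff) / np.sqrt(2), abs=1e-10)
        target = np.array([1.0, -1.0]) / np.sqrt(2)
        assert min(
            np.linalg.norm(U[:, 0] - target), np.linalg.norm(U[:, 0] + target)
        ) < 1e-10
        assert ev[0] == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_and_eigen_oracle(self, rng):
        M_c = rng.standard_normal((4, 6))
        M_c -= M_c.mean(0)
        U, S, V, ev = pls_svd(M_c)
        np.testing.assert_allclose(U @ np.diag(S) @ V.T, M_c, atol=1e-10)
        eigs = np.sort(np.linalg.eigvalsh(M_c @ M_c.T))[::-1]
        np.testing.assert_allclose(S**2, np.clip(eigs, 0, None), atol=1e-10)
        assert ev.sum() == pytest.approx(1.0, abs=1e-12)
        assert (np.diff(S) <= 1e-12).all()


class TestPermutationPvalue:
    def test_extreme_observed_gives_minimum_p(self, rng):
        # a huge planted effect: only a re-draw of the original partition
        # (or its label swap) can tie the observed s1, so p equals the
        # add-one minimum plus any such exact re-draws, recounted here
        X, cells = _two_group_data(rng, n_per_cell=10, effect=50.0)
        res = MeanCenteredPLS(X, cells).fit(n_permutations=99, n_bootstraps=10, rng=0)
        redraws = 0
        r = np.random.default_rng(0)  # permutation stream of fit(rng=0)
        for _ in range(99):
            perm = r.permutation(cells)
            if np.array_equal(perm, cells) or np.array_equal(perm, 1 - cells):
                redraws += 1
        assert res.p_value == pytest.approx((1 + redraws) / 100)

    def test_add_one_bounds(self, rng):
        X, cells = _two_group_data(rng, n_per_cell=4)
        for seed in range(5):
            res = MeanCenteredPLS(X, cells).fit(n_permutations=20, n_bootstraps=10, rng=seed)
            assert 1 / 21 <= res.p_value <= 1.0

    def test_exact_matches_exhaustive_enumeration_oracle(self, rng):
        # 4 rows, 2 cells: all C(4,2) = 6 assignments enumerated independently
        X = rng.standard_normal((4, 5))
        cells = np.array([0, 0, 1, 1])

        def s1_of(assign):
            M_c, _ = cell_mean_center(X, np.asarray(assign), 2)
            return np.linalg.svd(M_c, compute_uv=False)[0]

        s1_obs = s1_of(cells)
        perms = []
        for pos in combinations(range(4), 2):
            a = np.ones(4, dtype=int)
            a[list(pos)] = 0
            perms.append(s1_of(a))
        p_oracle = sum(s >= s1_obs - 1e-12 for s in perms) / 6

        res = MeanCenteredPLS(X, cells).fit(n_permutations="exact", n_bootstraps=10, rng=0)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-12)

    def test_degenerate_zero_matrix_p_one(self):
        X = np.ones((6, 3))
        res = MeanCenteredPLS(X, np.repeat([0, 1], 3)).fit(
            n_permutations=10, n_bootstraps=10, rng=0
        )
        assert res.p_value == 1.0

    def test_single_cell_rejected(self, rng):
        with pytest.raises(ValueError, match="2 design cells"):
            MeanCenteredPLS(rng.standard_normal((4, 3)), np.zeros(4, dtype=int), cells=["only"])


class TestBootstrapRatios:
    def test_sign_matches_reference_salience(self, rng):
        X, cells = _two_group_data(rng, n_per_cell=8, effect=1.0)
        res = MeanCenteredPLS(X, cells).fit(n_permutations=10, n_bootstraps=100, rng=0)
        v1 = res.feature_saliences[:, 0]
        nz = np.abs(v1) > 1e-9
        assert np.array_equal(np.sign(res.z_scores[nz]), np.sign(v1[nz]))

    def test_strongly_loaded_feature_exceeds_threshold(self):
        # one feature carries a 5-sigma cell effect, 20 subjects per cell:
        # its |z| clears 2.5 in at least 19 of 20 seeded replicates
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X, cells = _two_group_data(r, n_per_cell=20, n_features=6, effect=5.0)
            res = MeanCenteredPLS(X, cells).fit(n_permutations=5, n_bootstraps=200, rng=seed)
            hits += abs(res.z_scores[0]) > 2.5
        assert hits >= 19

    def test_small_cell_rejected(self, rng):
        X = rng.standard_normal((3, 4))
        cells = np.array([0, 0, 1])
        with pytest.raises(ValueError, match=">= 2 subjects"):
            MeanCenteredPLS(X, cells).fit(n_permutations=5, n_bootstraps=10, rng=0)


class TestSignAlignment:
    def test_median_z_nonnegative_and_idempotent(self, rng):
        X, cells = _two_group_data(rng, n_per_cell=6, effect=1.5)
        res = MeanCenteredPLS(X, cells).fit(n_permutations=10, n_bootstraps=50, rng=0)
        assert np.median(res.z_scores) >= 0
        before = (res.contrast.copy(), res.z_scores.copy(), res.sign_flipped)
        res._align_sign()
        np.testing.assert_array_equal(res.contrast, before[0])
        np.testing.assert_array_equal(res.z_scores, before[1])
        assert res.sign_flipped == before[2]

    def test_flip_negates_everything_consistently(self, rng):
        # construct a result whose median z is negative, then align
        X, cells = _two_group_data(rng, n_per_cell=6, effect=1.5)
        res = MeanCenteredPLS(X, cells).fit(n_permutations=10, n_bootstraps=50, rng=0)
        res.z_scores = -res.z_scores  # force the negative-median branch
        contrast0 = res.contrast.copy()
        flipped0 = res.sign_flipped
        res._align_sign()
        assert np.median(res.z_scores) >= 0
        np.testing.assert_array_equal(res.contrast, -contrast0)
        assert res.sign_flipped != flipped0


class TestInvariants:
    def test_fit_deterministic_given_seed(self, rng):
        X, cells = _two_group_data(rng, n_per_cell=6, effect=0.5)
        a = MeanCenteredPLS(X, cells).fit(n_permutations=50, n_bootstraps=50, rng=9)
        b = MeanCenteredPLS(X, cells).fit(n_permutations=50, n_bootstraps=50, rng=9)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.z_scores, b.z_scores)
        np.testing.assert_array_equal(a.contrast, b.contrast)

    def test_group_label_swap_symmetry(self, rng):
        X, cells = _two_group_data(rng, n_per_cell=6, effect=0.8)
        a = MeanCenteredPLS(X, cells).fit(n_permutations=200, n_bootstraps=100, rng=3)
        b = MeanCenteredPLS(X, 1 - cells).fit(n_permutations=200, n_bootstraps=100, rng=3)
        assert a.singular_values[0] == pytest.approx(b.singular_values[0], abs=1e-12)
        assert a.p_value == b.p_value
        np.testing.assert_allclose(np.abs(a.z_scores), np.abs(b.z_scores), atol=1e-9)
        # contrast under swapped labels is the row-swapped (possibly negated) original
        swapped = b.contrast[[1, 0]]
        assert min(
            np.linalg.norm(a.contrast - swapped), np.linalg.norm(a.contrast + swapped)
        ) < 1e-9

    def test_subject_scheme_keeps_conditions_together(self, rng):
        # 4-cell design: 2 groups x 2 conditions, rows paired by subject
        n = 6
        X = rng.standard_normal((4 * n, 5))
        cells = np.repeat([0, 1, 2, 3], n)
        subjects = [f"s{g}{i}" for g in (0, 1) for c in (0, 1) for i in range(n)]
        model = MeanCenteredPLS(X, cells, subjects=subjects, permute_scheme="subjects")
        perm = model._permuted_cells(np.random.default_rng(0))
        for s in set(subjects):
            rows = [i for i, x in enumerate(subjects) if x == s]
            src = sorted(model.row_cells[rows])
            dst = sorted(perm[rows])
            # a subject keeps one row per condition: cells {0,1} or {2,3}
            assert dst in ([0, 1], [2, 3]) and src in ([0, 1], [2, 3])
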