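"""Distance-correlation estimator against a literal brute-force oracle,
plus subsampling, pooling and tensor-level behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from connscreen.connectivity import (
    ConnectivityTensor,
    SubsampleConfig,
    compute_connectivity_tensor,
    distance_correlation,
    median_connectivity,
    pairwise_distance_correlation,
    subsample_estimates,
    substream,
)
from connscreen.timeseries import RunData, SubjectRecord
from oracles import dcor_bruteforce


class TestDistanceCorrelation:
    def test_self_correlation_is_one(self):
        assert distance_correlation([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_constant_series_convention(self):
        assert distance_correlation([1, 2, 3, 4], [7, 7, 7, 7]) == 0.0

    def test_matches_bruteforce_on_fixed_example(self):
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        assert distance_correlation(x, y) == pytest.approx(dcor_bruteforce(x, y), abs=1e-12)

    def test_matches_bruteforce_on_200_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 41))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n) + 0.5 * x
            assert distance_correlation(x, y) == pytest.approx(
                dcor_bruteforce(x, y), abs=1e-12
            )

    def test_length_mismatch_and_short_series_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            distance_correlation([1, 2, 3], [1, 2])
        with pytest.raises(ValueError, match="at least 2"):
            distance_correlation([1.0], [2.0])

    @settings(max_examples=50, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        shift=st.floats(-100, 100),
        scale=st.floats(0.01, 50),
    )
    def test_symmetry_shift_and_scale_invariance(self, seed, shift, scale):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal(12), r.standard_normal(12)
        d = distance_correlation(x, y)
        assert distance_correlation(y, x) == pytest.approx(d, abs=1e-12)
        assert distance_correlation(x + shift, y) == pytest.approx(d, abs=1e-9)
        assert distance_correlation(scale * x, y) == pytest.approx(d, abs=1e-9)

    def test_pairwise_agrees_with_scalar_version(self, rng):
        X = rng.standard_normal((20, 5))
        M = pairwise_distance_correlation(X)
        for i in range(5):
            for j in range(i + 1, 5):
                assert M[i, j] == pytest.approx(
                    distance_correlation(X[:, i], X[:, j]), abs=1e-12
                )
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)


class TestSubsampleEstimates:
    def test_full_sample_subsample_is_exact(self, rng):
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        cfg = SubsampleConfig(m=30, reps=5, seed=0)
        est = subsample_estimates(x, y, cfg, np.random.default_rng(0))
        assert np.all(est == distance_correlation(x, y))

    def test_reps_count_and_range(self, rng):
        x, y = rng.standard_normal(55), rng.standard_normal(55)
        cfg = SubsampleConfig(m=30, reps=100, seed=0)
        est = subsample_estimates(x, y, cfg, np.random.default_rng(1))
        assert est.shape == (100,)
        assert ((est >= 0) & (est <= 1)).all()

    def test_seeded_determinism(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        cfg = SubsampleConfig(m=30, reps=10, seed=0)
        a = subsample_estimates(x, y, cfg, np.random.default_rng(42))
        b = subsample_estimates(x, y, cfg, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_too_short_segment_rejected(self, rng):
        cfg = SubsampleConfig(m=30, reps=5, seed=0)
        with pytest.raises(ValueError, match="< subsample size"):
            subsample_estimates(rng.standard_normal(20), rng.standard_normal(20), cfg, rng)

    def test_bias_decreases_with_larger_subsample(self):
        # independent series: E[dCor] is a pure finite-sample bias that
        # shrinks as the subsample grows
        means = {}
        for m in (10, 30):
            vals = []
            for s in range(40):
                r = np.random.default_rng(1000 + s)
                x, y = r.standard_normal(60), r.standard_normal(60)
                cfg = SubsampleConfig(m=m, reps=20, seed=0)
                vals.append(np.median(subsample_estimates(x, y, cfg, np.random.default_rng(s))))
            means[m] = np.mean(vals)
        assert means[30] < means[10]


class TestMedianConnectivity:
    def test_pooled_median_of_two_runs(self, rng):
        a, b = rng.random(100), rng.random(100)
        assert median_connectivity([a, b]) == np.median(np.concatenate([a, b]))

    def test_constant_pool(self):
        assert median_connectivity([np.full(10, 0.4), np.full(3, 0.4)]) == 0.4

    def test_even_count_midpoint_convention(self):
        assert median_connectivity([np.array([0.1, 0.2]), np.array([0.4, 0.8])]) == pytest.approx(0.3)

    def test_order_invariance(self, rng):
        a, b = rng.random(7), rng.random(13)
        assert median_connectivity([a, b]) == median_connectivity([b, a[::-1]])

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="no estimates"):
            median_connectivity([np.array([]), np.array([])])


def _cohort_from_matrix(data_by_run, labels_by_run, subject_id="sub-01", group="TD"):
    runs = [RunData(d, l) for d, l in zip(data_by_run, labels_by_run)]
    return [SubjectRecord(subject_id, group, runs)]


class TestConnectivityTensor:
    def test_edge_count_and_range(self, four_roi_map, rng):
        labels = ["baseline"] * 34 + ["semantic"] * 32 + ["pragmatic"] * 32
        cohort = _cohort_from_matrix(
            [rng.standard_normal((98, 4))], [labels]
        )
        cfg = SubsampleConfig(m=30, reps=10, seed=3)
        t = compute_connectivity_tensor(cohort, four_roi_map, cfg)
        assert t.values.shape == (1, 3, 6)  # 4 ROIs -> 6 edges
        assert ((t.values >= 0) & (t.values <= 1)).all()

    def test_duplicated_column_gives_unit_edge(self, four_roi_map, rng):
        base = rng.standard_normal((98, 4))
        base[:, 1] = base[:, 0]
        labels = ["baseline"] * 34 + ["semantic"] * 32 + ["pragmatic"] * 32
        cohort = _cohort_from_matrix([base], [labels])
        t = compute_connectivity_tensor(cohort, four_roi_map, SubsampleConfig(m=30, reps=5, seed=0))
        edge01 = 0  # edge (0, 1) is first in canonical order
        np.testing.assert_allclose(t.values[0, :, edge01], 1.0)

    def test_min_length_error_names_context(self, four_roi_map, rng):
        labels = ["baseline"] * 20 + ["semantic"] * 40 + ["pragmatic"] * 40
        cohort = _cohort_from_matrix([rng.standard_normal((100, 4))], [labels])
        with pytest.raises(ValueError, match="sub-01 run 0 condition 'baseline'"):
            compute_connectivity_tensor(cohort, four_roi_map, SubsampleConfig(m=30, reps=5, seed=0))

    def test_share_indices_modes_agree_in_distribution(self, rng):
        # both modes give identical per-edge marginals; with m == n they
        # coincide exactly because every subsample is the full segment
        from connscreen.atlas import ParcellationMap

        pmap = ParcellationMap([1, 2, 3], ["LH_A"] * 3, ["L"] * 3)
        labels = ["baseline"] * 30 + ["semantic"] * 30 + ["pragmatic"] * 30
        data = rng.standard_normal((90, 3))
        for share in (True, False):
            cfg = SubsampleConfig(m=30, reps=4, share_indices=share, seed=5)
            t = compute_connectivity_tensor(_cohort_from_matrix([data], [labels]), pmap, cfg)
            full = pairwise_distance_correlation(data[:30])
            np.testing.assert_allclose(t.values[0, 0], full[np.triu_indices(3, 1)], atol=1e-12)

    def test_deterministic_given_seed_and_subject_order(self, tiny_cohort):
        cohort, pmap = tiny_cohort
        cfg = SubsampleConfig(m=30, reps=5, seed=11)
        t1 = compute_connectivity_tensor(cohort, pmap, cfg)
        t2 = compute_connectivity_tensor(list(reversed(cohort)), pmap, cfg)
        for s, sid in enumerate(t1.subjects):
            np.testing.assert_array_equal(
                t1.values[s], t2.values[t2.subjects.index(sid)]
            )

    def test_tensor_tsv_roundtrip(self, tiny_tensor, tmp_path):
        t, pmap = tiny_tensor
        t.save(tmp_path / "tensor", pmap)
        back = ConnectivityTensor.load(tmp_path / "tensor")
        np.testing.assert_allclose(back.values, t.values, atol=1e-9)
        assert back.subjects == t.subjects
        assert back.groups == t.groups
        assert back.conditions == t.conditions


def test_substream_is_order_independent():
    a = substream(5, "conn", "sub-01", 0, "baseline").random(3)
    b = substream(5, "conn", "sub-01", 0, "baseline").random(3)
    c = substream(5, "conn", "sub-02", 0, "baseline").random(3)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
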