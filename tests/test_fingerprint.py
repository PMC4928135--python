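"""Voxel normalization and fingerprint assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import connfp as cf
from conftest import brute_force_fingerprint


class TestVoxelProbabilities:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([2, 2, 0], [0.5, 0.5, 0.0]),
            ([5000, 0, 0], [1.0, 0.0, 0.0]),
            ([1, 2, 3], [1 / 6, 2 / 6, 3 / 6]),
        ],
    )
    def test_normalizes_to_voxel_total(self, row, expected):
        np.testing.assert_allclose(cf.voxel_probabilities(np.array(row)), expected)

    def test_all_zero_row_is_degenerate(self):
        with pytest.raises(cf.DegenerateVoxelError):
            cf.voxel_probabilities(np.zeros(4))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cf.voxel_probabilities(np.array([1, -1, 2]))


class TestComputeFingerprint:
    def test_average_of_per_voxel_probabilities(self):
        # voxel [2,2,0] -> [.5,.5,0]; voxel [0,4,0] -> [0,1,0]; average below
        vc = cf.VoxelCounts(seed=2, counts=np.array([[2, 2, 0], [0, 4, 0]]))
        np.testing.assert_allclose(cf.compute_fingerprint(vc).w, [0.25, 0.75, 0.0])

    def test_single_uniform_voxel(self):
        vc = cf.VoxelCounts(seed=4, counts=np.array([[1, 1, 1, 1, 0]]))
        np.testing.assert_allclose(cf.compute_fingerprint(vc).w, [0.25] * 4 + [0.0])

    def test_differs_from_pooled_count_normalization(self):
        # unequal voxel totals: per-voxel averaging weights voxels equally,
        # pooling weights them by total count
        counts = np.array([[1, 1, 0], [98, 2, 0]])
        vc = cf.VoxelCounts(seed=2, counts=counts)
        averaged = cf.compute_fingerprint(vc).w
        pooled = counts.sum(axis=0) / counts.sum()
        np.testing.assert_allclose(averaged[:2], [0.74, 0.26])  # avg of .5/.98, .5/.02
        assert not np.allclose(averaged, pooled)

    def test_equals_pooling_when_voxel_totals_equal(self):
        rng = np.random.default_rng(0)
        counts = rng.multinomial(100, [0.3, 0.3, 0.4, 0.0], size=5)
        vc = cf.VoxelCounts(seed=3, counts=counts)
        pooled = counts.sum(axis=0) / counts.sum()
        np.testing.assert_allclose(cf.compute_fingerprint(vc).w, pooled, atol=1e-12)

    def test_matches_brute_force_oracle_on_random_counts(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = rng.integers(2, 7)
            n_vox = rng.integers(1, 6)
            seed = int(rng.integers(m))
            counts = rng.integers(0, 50, size=(n_vox, m))
            counts[:, seed] = 0
            if not (counts.sum(axis=1) > 0).any():
                continue
            vc = cf.VoxelCounts(seed=seed, counts=counts)
            np.testing.assert_allclose(
                cf.compute_fingerprint(vc).w,
                brute_force_fingerprint(counts, seed),
                atol=1e-12,
            )

    def test_zero_total_voxels_excluded_with_log(self, caplog):
        counts = np.array([[0, 4, 4], [0, 0, 0]])
        vc = cf.VoxelCounts(seed=0, counts=counts)
        with caplog.at_level("WARNING", logger="connfp"):
            w = cf.compute_fingerprint(vc).w
        np.testing.assert_allclose(w, [0.0, 0.5, 0.5])
        assert "zero-total" in caplog.text

    def test_all_voxels_degenerate_names_seed(self):
        vc = cf.VoxelCounts(seed=1, counts=np.zeros((3, 4), dtype=int))
        with pytest.raises(cf.DegenerateVoxelError, match="1"):
            cf.compute_fingerprint(vc)

    @settings(deadline=None, max_examples=50)
    @given(
        counts=st.lists(
            st.lists(st.integers(1, 40), min_size=4, max_size=4),
            min_size=1,
            max_size=5,
        ),
        scale=st.integers(2, 9),
    )
    def test_sums_to_one_and_scale_invariant(self, counts, scale):
        c = np.array(counts)
        c = np.column_stack([np.zeros(len(c), dtype=int), c])  # seed col 0
        w = cf.compute_fingerprint(cf.VoxelCounts(seed=0, counts=c)).w
        assert abs(w.sum() - 1) < 1e-12
        w_scaled = cf.compute_fingerprint(cf.VoxelCounts(seed=0, counts=c * scale)).w
        np.testing.assert_allclose(w, w_scaled, atol=1e-12)


class TestFingerprintMatrix:
    def test_rows_are_per_seed_fingerprints(self, atlas6, small_cohort):
        fm = cf.build_fingerprint_matrix(
            list(small_cohort.voxel_counts[0]), small_cohort.atlas
        )
        assert fm.W.shape == (6, 6)
        np.testing.assert_allclose(np.diag(fm.W), 0)
        np.testing.assert_allclose(fm.W.sum(axis=1), 1, atol=1e-12)

    def test_nodal_normalization_is_asymmetric(self):
        # node 1 propagates far more samples overall than node 0, so the
        # probability seen from node 0 exceeds the one seen from node 1
        atlas = cf.RegionAtlas(labels=("a", "b", "c"))
        vc0 = cf.VoxelCounts(seed=0, counts=np.array([[0, 5, 5]]))
        vc1 = cf.VoxelCounts(seed=1, counts=np.array([[5, 0, 95]]))
        vc2 = cf.VoxelCounts(seed=2, counts=np.array([[5, 5, 0]]))
        fm = cf.build_fingerprint_matrix([vc0, vc1, vc2], atlas)
        assert fm.W[0, 1] > fm.W[1, 0]

    def test_missing_and_duplicate_seeds_reported(self, atlas6):
        vc = cf.VoxelCounts(seed=0, counts=np.array([[0, 1, 1, 1, 1, 1]]))
        with pytest.raises(ValueError, match="missing"):
            cf.build_fingerprint_matrix([vc], atlas6)
        with pytest.raises(ValueError, match="duplicate"):
            cf.build_fingerprint_matrix([vc, vc], atlas6)

    def test_simulator_cohort_rows_sum_to_one(self, small_cohort):
        coh = small_cohort.fingerprints()
        np.testing.assert_allclose(coh.W_stack.sum(axis=2), 1, atol=1e-12)


class TestRegionCountFallback:
    def test_row_normalization(self):
        C = np.array([[0, 3, 1], [2, 0, 2], [1, 1, 0]])
        fm = cf.fingerprint_from_region_counts(C)
        np.testing.assert_allclose(
            fm.W, [[0, 0.75, 0.25], [0.5, 0, 0.5], [0.5, 0.5, 0]]
        )

    def test_one_hot_rows(self):
        C = np.array([[0, 7, 0], [0, 0, 3], [2, 0, 0]])
        fm = cf.fingerprint_from_region_counts(C)
        np.testing.assert_allclose(fm.W, [[0, 1, 0], [0, 0, 1], [1, 0, 0]])

    def test_zero_row_warns_and_stays_zero(self):
        C = np.array([[0, 1, 1], [0, 0, 0], [1, 1, 0]])
        with pytest.warns(UserWarning, match="zero-count"):
            fm = cf.fingerprint_from_region_counts(C)
        np.testing.assert_allclose(fm.W[1], 0)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            cf.fingerprint_from_region_counts(np.array([[0, -1], [1, 0]]))
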