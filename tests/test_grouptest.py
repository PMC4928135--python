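"""Within-vs-between-group similarity permutation test and FDR."""

import itertools

import numpy as np
import pytest

import connfp as cf
from connfp.grouptest import count_distinct_relabelings
from connfp.similarity import SimilarityStack


def brute_force_test(S: np.ndarray, labels: tuple[str, ...]) -> tuple[float, float]:
    """Independent oracle: enumerate every distinct relabeling with loops."""

    def stat(lab):
        within, between = [], []
        n = len(lab)
        for i in range(n):
            for j in range(i + 1, n):
                (within if lab[i] == lab[j] else between).append(S[i, j])
        return np.mean(within) - np.mean(between)

    t_obs = stat(labels)
    all_labs = sorted(set(itertools.permutations(labels)))
    t_all = [stat(lab) for lab in all_labs]
    p = sum(t >= t_obs - 1e-12 for t in t_all) / len(t_all)
    return t_obs, p


def random_similarity(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    S = rng.uniform(0.1, 1, size=(n, n))
    S = (S + S.T) / 2
    np.fill_diagonal(S, 1.0)
    return S


class TestGroupStatistic:
    def test_constant_matrix_gives_zero(self):
        S = np.full((6, 6), 0.3)
        np.fill_diagonal(S, 1.0)
        design = cf.GroupDesign(labels=("a",) * 3 + ("b",) * 3)
        assert cf.group_statistic(S, design) == pytest.approx(0.0)

    def test_hand_example_2plus2(self):
        # within pairs (0,1) and (2,3) = 1.0; the four between pairs = 0.5
        S = np.full((4, 4), 0.5)
        S[0, 1] = S[1, 0] = S[2, 3] = S[3, 2] = 1.0
        np.fill_diagonal(S, 1.0)
        design = cf.GroupDesign(labels=("a", "a", "b", "b"))
        assert cf.group_statistic(S, design) == pytest.approx(0.5)

    def test_invariant_to_group_label_swap(self):
        S = random_similarity(6, 1)
        d1 = cf.GroupDesign(labels=("a", "a", "a", "b", "b", "b"))
        d2 = cf.GroupDesign(labels=("b", "b", "b", "a", "a", "a"))
        assert cf.group_statistic(S, d1) == pytest.approx(cf.group_statistic(S, d2))

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            cf.GroupDesign(labels=("a", "a", "b"))

    def test_matches_oracle(self):
        S = random_similarity(7, 2)
        labels = ("a", "a", "a", "b", "b", "b", "b")
        t = cf.group_statistic(S, cf.GroupDesign(labels=labels))
        assert t == pytest.approx(brute_force_test(S, labels)[0])


class TestPermutationPvalue:
    @pytest.mark.parametrize("sizes", [(3, 3), (4, 3), (2, 2, 2)])
    def test_exhaustive_matches_brute_force(self, sizes):
        labels = tuple(
            g for name, k in zip("abc", sizes) for g in [name] * k
        )
        S = random_similarity(len(labels), seed=sum(sizes))
        design = cf.GroupDesign(labels=labels)
        t, p = cf.permutation_pvalue(S, design, N=50_000, seed=0)
        t_ref, p_ref = brute_force_test(S, labels)
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_monte_carlo_agrees_with_exhaustive_within_3se(self):
        labels = ("a",) * 5 + ("b",) * 5
        S = random_similarity(10, seed=9)
        design = cf.GroupDesign(labels=labels)
        _, p_exact = brute_force_test(S, labels)
        N = 20_000
        _, p_mc = cf.permutation_pvalue(S, design, N=N, seed=3, exhaustive=False)
        se = np.sqrt(p_exact * (1 - p_exact) / N)
        assert abs(p_mc - p_exact) <= 3 * se + 1 / N

    def test_p_has_lower_bound_one_over_N(self):
        # strong group structure: p attains but never goes below 1/N_distinct
        S = np.full((6, 6), 0.1)
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            S[i, j] = S[j, i] = 0.95
        np.fill_diagonal(S, 1.0)
        design = cf.GroupDesign(labels=("a",) * 3 + ("b",) * 3)
        _, p = cf.permutation_pvalue(S, design, N=50_000, seed=0)
        assert p == pytest.approx(2 / 20)  # complement relabeling ties

    def test_exchangeable_duplicate_labels_give_p_one(self):
        S = np.full((4, 4), 0.5)
        np.fill_diagonal(S, 1.0)
        design = cf.GroupDesign(labels=("a", "a", "b", "b"))
        _, p = cf.permutation_pvalue(S, design, N=1000, seed=0)
        assert p == 1.0

    def test_relabeling_count(self):
        assert count_distinct_relabelings(np.array([0, 0, 0, 1, 1, 1])) == 20
        assert count_distinct_relabelings(np.array([0, 0, 1, 1, 2, 2])) == 90


class TestTestAllNodes:
    def _sim_stack(self, cohort):
        coh = cohort.fingerprints()
        return coh, cf.similarity_stack(coh, cf.compute_alpha(coh))

    def test_table_contract_and_determinism(self, small_cohort):
        coh, sim = self._sim_stack(small_cohort)
        t1 = cf.test_all_nodes(sim, small_cohort.design, N=500, seed=4)
        t2 = cf.test_all_nodes(sim, small_cohort.design, N=500, seed=4)
        assert t1.equals(t2)
        assert set(t1.columns) == {"node", "T", "p", "q", "reject"}
        assert (t1["p"] >= 1 / t1.attrs["n_relabelings"]).all()
        assert (t1["q"] >= t1["p"] - 1e-15).all()

    def test_planted_node_detected(self, effect_cohort):
        coh, sim = self._sim_stack(effect_cohort)
        table = cf.test_all_nodes(sim, effect_cohort.design, N=2000, seed=0)
        assert bool(table["reject"].iloc[2])

    def test_three_group_comparison_runs(self):
        spec = cf.SimCohortSpec(
            m=5, voxels_per_region=3, samples_per_voxel=200,
            n_per_group=(3, 3, 3), seed=2,
        )
        co = cf.generate_cohort(spec)
        coh = co.fingerprints()
        sim = cf.similarity_stack(coh, cf.compute_alpha(coh))
        table = cf.test_all_nodes(sim, co.design, N=200, seed=1)
        assert len(table) == 5
        assert table["p"].between(0, 1).all()


class TestFdrAdjust:
    def bh_oracle(self, p):
        """Step-up BH by definition."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q[i] = running
        return q

    @pytest.mark.parametrize(
        "pvals",
        [
            [0.01, 0.02, 0.03, 0.04],
            [0.001, 0.9],
            [0.04],
            [0.01, 0.01, 0.7, 0.2, 0.06],
        ],
    )
    def test_matches_step_up_oracle(self, pvals):
        q, reject = cf.fdr_adjust(np.array(pvals), 0.05)
        np.testing.assert_allclose(q, self.bh_oracle(pvals), atol=1e-12)
        np.testing.assert_array_equal(reject, q <= 0.05)

    def test_known_adjustments(self):
        q, reject = cf.fdr_adjust(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        assert reject.all()
        q2, _ = cf.fdr_adjust(np.array([0.001, 0.9]), 0.05)
        np.testing.assert_allclose(q2, [0.002, 0.9])

    def test_equal_pvalues_all_rejected(self):
        q, reject = cf.fdr_adjust(np.full(20, 0.01), 0.05)
        assert reject.all()

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError):
            cf.fdr_adjust(np.array([]), 0.05)
        with pytest.raises(ValueError):
            cf.fdr_adjust(np.array([0.0, 0.5]), 0.05)
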