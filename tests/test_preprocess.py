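import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from percolome.core import ConnectomeError
from percolome.preprocess import (
    binarize,
    binary_subtract,
    edge_budget,
    group_average,
    n_pairs,
    normalize,
    threshold_proportional,
)

from conftest import make_matrix


def random_raw(n, seed, distinct=True):
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1, 1, (n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return make_matrix(w, state="raw")


class TestGroupAverage:
    def test_single_matrix_identity(self):
        m = random_raw(6, 0)
        avg = group_average([m])
        np.testing.assert_array_equal(avg.weights, m.weights)

    def test_two_matrix_mean(self):
        a = make_matrix([[0, 0.2], [0.2, 0]], state="raw")
        b = make_matrix([[0, 0.4], [0.4, 0]], state="raw")
        assert group_average([a, b]).weights[0, 1] == pytest.approx(0.3)

    def test_matches_brute_force_mean(self, default_cohort):
        _, control, _, _ = default_cohort
        avg = group_average(control)
        expected = sum(m.weights for m in control) / len(control)
        np.testing.assert_allclose(avg.weights, expected, atol=1e-12)

    def test_label_mismatch_rejected(self):
        a = make_matrix(np.zeros((2, 2)), state="raw", labels=("a", "b"))
        b = make_matrix(np.zeros((2, 2)), state="raw", labels=("a", "c"))
        with pytest.raises(ConnectomeError, match="label"):
            group_average([a, b])


class TestNormalize:
    def test_scales_by_max_and_clips_negatives(self):
        m = make_matrix(
            [[0, 0.8, 0.4], [0.8, 0, -0.2], [0.4, -0.2, 0]], state="raw"
        )
        out = normalize(m)
        np.testing.assert_allclose(
            out.weights, [[0, 1.0, 0.5], [1.0, 0, 0.0], [0.5, 0.0, 0]]
        )
        assert out.state == "normalized"

    def test_all_zero_stays_zero(self):
        out = normalize(make_matrix(np.zeros((4, 4)), state="raw"))
        assert not out.weights.any()

    @pytest.mark.parametrize("seed", range(20))
    def test_unit_max_nonnegative(self, seed):
        out = normalize(random_raw(12, seed))
        assert out.weights.max() == pytest.approx(1.0)
        assert out.weights.min() >= 0.0


class TestThresholdProportional:
    def test_90_node_10pct_arithmetic(self):
        m = normalize(random_raw(90, 7))
        out = threshold_proportional(m, 0.10)
        assert out.n_edges == 401
        assert out.density == pytest.approx(0.1001, abs=5e-5)
        assert 2 * out.n_edges / out.n == pytest.approx(8.911, abs=5e-4)

    def test_full_density_keeps_strictly_positive_matrix(self):
        w = np.full((5, 5), 0.5)
        np.fill_diagonal(w, 0.0)
        m = make_matrix(w, state="normalized")
        out = threshold_proportional(m, 1.0)
        np.testing.assert_array_equal(out.weights, m.weights)

    def test_top_edges_match_sort_oracle(self):
        rng = np.random.default_rng(11)
        n = 5
        w = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        vals = rng.permutation(np.linspace(0.05, 1.0, len(iu[0])))
        w[iu] = vals
        w += w.T
        m = make_matrix(w, state="normalized")
        out = threshold_proportional(m, 0.3)
        budget = edge_budget(0.3, n)
        expected = set(
            map(tuple, np.array(iu).T[np.argsort(-vals)][:budget].tolist())
        )
        kept = set(zip(*np.nonzero(np.triu(out.weights, k=1))))
        assert kept == expected

    def test_tie_break_prefers_low_indices(self):
        w = np.zeros((4, 4))
        iu = np.triu_indices(4, k=1)
        w[iu] = 0.5  # all six edges tie
        w += w.T
        out = threshold_proportional(make_matrix(w, state="normalized"), 0.5)
        # budget = 3 of 6; lexicographically first pairs win
        kept = sorted(zip(*np.nonzero(np.triu(out.weights, k=1))))
        assert kept == [(0, 1), (0, 2), (0, 3)]

    @pytest.mark.parametrize("density", [0.0, -0.1, 1.5])
    def test_invalid_density_rejected(self, density):
        m = normalize(random_raw(5, 0))
        with pytest.raises(ConnectomeError, match="density"):
            threshold_proportional(m, density)

    @pytest.mark.parametrize("seed", range(5))
    def test_never_increases_weights_keeps_symmetry(self, seed):
        m = normalize(random_raw(10, seed))
        out = threshold_proportional(m, 0.2)
        assert np.all(out.weights <= m.weights + 1e-15)
        np.testing.assert_array_equal(out.weights, out.weights.T)
        assert np.all(np.diag(out.weights) == 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_density_monotonicity_nested_edge_sets(self, seed):
        m = normalize(random_raw(12, seed))
        lo = threshold_proportional(m, 0.1)
        hi = threshold_proportional(m, 0.4)
        lo_edges = set(zip(*np.nonzero(np.triu(lo.weights, k=1))))
        hi_edges = set(zip(*np.nonzero(np.triu(hi.weights, k=1))))
        assert lo_edges <= hi_edges

    @given(st.integers(min_value=2, max_value=30), st.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_edge_budget_rounds_half_away_from_zero(self, n, density):
        budget = edge_budget(density, n)
        target = density * n_pairs(n)
        assert budget == int(np.floor(target + 0.5))

    def test_half_case_rounds_up(self):
        assert edge_budget(0.10, 90) == 401  # 400.5 -> 401


class TestBinarize:
    def test_nonzero_to_one(self):
        m = make_matrix([[0, 0.3, 0], [0.3, 0, 1.0], [0, 1.0, 0]])
        out = binarize(m)
        np.testing.assert_array_equal(
            out.weights, [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        )
        assert out.state == "binarized"

    def test_thresholded_90_node_has_401_ones(self, control_average):
        out = binarize(control_average)
        assert int(np.triu(out.weights, k=1).sum()) == 401


class TestBinarySubtract:
    def test_identical_networks_all_zero_shared_equals_input(self):
        m = binarize(make_matrix([[0, 0.4], [0.4, 0]]))
        diff, shared = binary_subtract(m, m)
        assert not diff.any()
        np.testing.assert_array_equal(shared, m.weights)

    def test_exclusive_edge_signs(self):
        a = binarize(make_matrix([[0, 0.4, 0], [0.4, 0, 0], [0, 0, 0]]))
        b = binarize(make_matrix([[0, 0, 0], [0, 0, 0.6], [0, 0.6, 0]]))
        diff, shared = binary_subtract(a, b)
        assert diff[0, 1] == 1 and diff[1, 2] == -1
        assert not shared.any()

    def test_set_algebra_on_group_averages(self, default_cohort):
        from percolome.pipeline import preprocess_group

        _, control, disease, _ = default_cohort
        a = binarize(preprocess_group(control, 0.10))
        b = binarize(preprocess_group(disease, 0.10))
        diff, shared = binary_subtract(a, b)
        iu = np.triu_indices(a.n, k=1)
        only_a = int((diff[iu] == 1).sum())
        only_b = int((diff[iu] == -1).sum())
        both = int(shared[iu].sum())
        union = int(((a.weights[iu] != 0) | (b.weights[iu] != 0)).sum())
        assert only_a + only_b + both == union

    def test_state_mismatch_rejected(self, control_average):
        with pytest.raises(ConnectomeError):
            binary_subtract(control_average, control_average)
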