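import numpy as np
import pytest

from daytrace.core import MISSING
from daytrace.patterns import (
    build_day_graph,
    cluster_profile,
    day_distance,
    eo_modularity,
    kmeans_days,
    modularity,
    one_hot_days,
)

from _oracles import best_partition_bruteforce, modularity_pairsum
from conftest import make_matrix


def two_clique_bridge(n_per=5, w_in=1.0, w_bridge=0.05):
    n = 2 * n_per
    w = np.zeros((n, n))
    for block in (range(n_per), range(n_per, n)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = w_in
    w[0, n_per] = w[n_per, 0] = w_bridge
    return w


class TestDayDistance:
    def test_identical_zero(self):
        d = ["A"] * 24
        assert day_distance(d, d) == 0.0

    def test_all_differ_unit_weights(self):
        assert day_distance(["A"] * 24, ["B"] * 24) == 24.0

    def test_single_weighted_slot(self):
        weights = [0.5] + [1.0] * 23
        d1 = ["A"] + ["H"] * 23
        d2 = ["B"] + ["H"] * 23
        assert day_distance(d1, d2, weights) == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            day_distance(["A"] * 24, ["A"] * 12)

    def test_missing_renormalization(self):
        # 12 comparable slots, 6 mismatches -> rescaled to 24-slot scale
        d1 = ["A"] * 6 + ["B"] * 6 + [MISSING] * 12
        d2 = ["A"] * 6 + ["C"] * 6 + ["D"] * 12
        assert day_distance(d1, d2) == pytest.approx(6 * 24 / 12)

    def test_no_overlap_maximal(self):
        d1 = ["A"] * 12 + [MISSING] * 12
        d2 = [MISSING] * 12 + ["A"] * 12
        assert day_distance(d1, d2) == 24.0


class TestDayGraph:
    def test_weight_formula_points(self, two_pattern_matrix):
        g = build_day_graph(two_pattern_matrix, delta=6.0)
        # identical days (rows 0 and 2) -> w = 1
        assert g.weights[0, 2] == pytest.approx(1.0)
        d = day_distance(two_pattern_matrix.slots[0], two_pattern_matrix.slots[1])
        assert g.weights[0, 1] == pytest.approx(np.exp(-d / 6.0))

    def test_distance_delta_gives_inverse_e(self):
        rows = [["A"] * 4 + ["H"] * 20, ["B"] * 4 + ["H"] * 20]
        g = build_day_graph(make_matrix(rows), delta=4.0)
        assert g.weights[0, 1] == pytest.approx(np.exp(-1.0))

    def test_monotone_in_distance(self):
        rows = [["H"] * 24, ["A"] * 4 + ["H"] * 20, ["A"] * 10 + ["H"] * 14]
        g = build_day_graph(make_matrix(rows))
        assert g.weights[0, 1] > g.weights[0, 2]

    def test_bad_delta(self, two_pattern_matrix):
        with pytest.raises(ValueError):
            build_day_graph(two_pattern_matrix, delta=0.0)

    def test_weights_bounds(self, two_pattern_matrix):
        g = build_day_graph(two_pattern_matrix)
        off = g.weights[~np.eye(g.n_days, dtype=bool)]
        assert ((off > 0) & (off <= 1)).all()

    def test_networkx_export(self, two_pattern_matrix):
        g = build_day_graph(two_pattern_matrix)
        nxg = g.to_networkx()
        assert nxg.number_of_nodes() == g.n_days
        assert nxg[0][1]["weight"] == pytest.approx(g.weights[0, 1])


class TestModularity:
    def test_matches_pairsum_oracle(self, rng):
        w = rng.random((8, 8))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        labels = rng.integers(0, 3, size=8)
        assert modularity(w, labels) == pytest.approx(
            modularity_pairsum(w, labels), abs=1e-12
        )


class TestEOModularity:
    def test_two_cliques_equal_bruteforce(self):
        w = two_clique_bridge()
        a = eo_modularity(w, rng=np.random.default_rng(0), restarts=8)
        q_star, labels_star = best_partition_bruteforce(w)
        assert a.score == pytest.approx(q_star, abs=1e-9)
        assert a.n_clusters == len(set(labels_star)) == 2

    def test_uniform_complete_graph_single_cluster(self):
        n = 8
        w = np.ones((n, n)) - np.eye(n)
        a = eo_modularity(w, rng=np.random.default_rng(0))
        assert a.n_clusters == 1
        assert a.score == pytest.approx(0.0, abs=1e-12)

    def test_single_vertex(self):
        a = eo_modularity(np.zeros((1, 1)), rng=np.random.default_rng(0))
        assert a.n_clusters == 1

    def test_beats_trivial_partition(self, rng):
        w = rng.random((20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        a = eo_modularity(w, rng=np.random.default_rng(0))
        assert a.score >= 0.0

    def test_fixed_seed_deterministic(self):
        w = two_clique_bridge()
        a1 = eo_modularity(w, rng=np.random.default_rng(5))
        a2 = eo_modularity(w, rng=np.random.default_rng(5))
        assert (a1.labels == a2.labels).all() and a1.score == a2.score


class TestKMeansDays:
    def test_exact_separation(self, two_pattern_matrix):
        a = kmeans_days(two_pattern_matrix, 2, n_runs=10)
        labels = a.labels
        assert len(set(labels[::2])) == 1 and len(set(labels[1::2])) == 1
        assert labels[0] != labels[1]
        assert a.score == pytest.approx(0.0, abs=1e-9)  # zero inertia

    def test_k1_total_variance(self, two_pattern_matrix):
        a = kmeans_days(two_pattern_matrix, 1, n_runs=1)
        x, _ = one_hot_days(two_pattern_matrix)
        total_var = ((x - x.mean(axis=0)) ** 2).sum()
        assert -a.score == pytest.approx(total_var)

    def test_best_of_runs_dominates_singles(self, rng):
        rows = rng.choice(list("ABCDEF"), size=(30, 24)).tolist()
        dm = make_matrix(rows)
        best = kmeans_days(dm, 4, n_runs=50, random_state=0)
        singles = [
            kmeans_days(dm, 4, n_runs=1, random_state=s).score for s in range(8)
        ]
        assert all(best.score >= s - 1e-9 for s in singles)

    def test_k_bounds(self, two_pattern_matrix):
        with pytest.raises(ValueError):
            kmeans_days(two_pattern_matrix, 0)
        with pytest.raises(ValueError):
            kmeans_days(two_pattern_matrix, 11)


class TestClusterProfile:
    def test_identical_cluster(self):
        dm = make_matrix([["A"] * 24] * 4)
        a = kmeans_days(dm, 1, n_runs=1)
        prof = cluster_profile(dm, a)
        assert list(prof.average_days[0]) == ["A"] * 24
        assert not prof.deviation_masks.any()

    def test_single_deviating_slot(self):
        rows = [["A"] * 24, ["A"] * 24, ["A"] * 24]
        rows[2][7] = "B"
        dm = make_matrix(rows)
        a = kmeans_days(dm, 1, n_runs=1)
        prof = cluster_profile(dm, a)
        assert prof.deviation_masks[2, 7]
        assert prof.deviation_masks.sum() == 1

    def test_day_reordering_invariance(self, two_pattern_matrix, rng):
        a = kmeans_days(two_pattern_matrix, 2, n_runs=10, random_state=0)
        perm = rng.permutation(two_pattern_matrix.n_days)
        shuffled = make_matrix(two_pattern_matrix.slots[perm].tolist())
        b = kmeans_days(shuffled, 2, n_runs=10, random_state=0)
        # same blocks up to label swap
        ref = a.labels[perm]
        same = (ref == b.labels).all() or (ref == 1 - b.labels).all()
        assert same
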