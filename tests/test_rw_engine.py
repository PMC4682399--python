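import numpy as np
import pytest

from argwalker import (
    ArgValidationError,
    backward_weights,
    forward_walk,
    load_arg,
    transition_matrix,
    walk_profile,
)
from argwalker.rw_engine import read_profile, write_profile

from conftest import random_dag
from oracles import leaf_mass_oracle, weight_oracle


class TestBackwardWeights:
    def test_chain_subtree_sizes(self):
        g = load_arg([(0, 1), (1, 2)], {2: "h"})
        w = backward_weights(g)
        assert w.w == {(1, 2): 1, (0, 1): 2}

    def test_star_symmetry(self):
        g = load_arg([(0, 1), (0, 2)], {1: "a", 2: "b"})
        assert backward_weights(g).w == {(0, 1): 1, (0, 2): 1}

    def test_six_node_double_counting(self, six_node_graph):
        w = backward_weights(six_node_graph).w
        assert w == {(2, 3): 1, (2, 4): 1, (0, 2): 3, (1, 2): 3, (0, 5): 1}

    def test_integer_weights_match_reachability_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            g = random_dag(rng, 10)
            w = backward_weights(g).w
            expected = weight_oracle(list(g.edges))
            assert w == expected
            assert all(isinstance(v, int) and v >= 1 for v in w.values())

    def test_grafting_a_subtree_increases_upstream_weight(self):
        base = load_arg([(0, 1), (1, 2), (1, 3)], {2: "a", 3: "b"})
        grown = load_arg([(0, 1), (1, 2), (1, 3), (3, 4), (3, 5)], {2: "a", 4: "c", 5: "d"})
        w0 = backward_weights(base).w
        w1 = backward_weights(grown).w
        assert w1[(0, 1)] > w0[(0, 1)]
        assert w1[(1, 3)] > w0[(1, 3)]


class TestTransitionMatrix:
    def test_star_equal_split(self):
        g = load_arg([(0, 1), (0, 2)], {1: "a", 2: "b"})
        t = transition_matrix(backward_weights(g)).t
        assert t == {(0, 1): 0.5, (0, 2): 0.5}

    def test_six_node_ratios(self, six_node_graph):
        t = transition_matrix(backward_weights(six_node_graph)).t
        assert t[(0, 2)] == pytest.approx(0.75)
        assert t[(0, 5)] == pytest.approx(0.25)
        assert t[(1, 2)] == 1.0

    def test_chain_all_ones_and_rows_stochastic(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            g = random_dag(rng, 12)
            t = transition_matrix(backward_weights(g)).t
            rows = {}
            for (u, _), p in t.items():
                rows[u] = rows.get(u, 0.0) + p
            assert all(abs(s - 1) < 1e-12 for s in rows.values())


class TestForwardWalk:
    def test_chain_all_mass_to_single_leaf(self):
        g = load_arg([(0, 1), (1, 2)], {2: "h"})
        prof = walk_profile(g)
        assert prof.strengths == {"h": 2.0}
        assert prof.probabilities == {"h": 1.0}

    def test_six_node_worked_example(self, six_node_graph):
        prof = walk_profile(six_node_graph)
        assert prof.strengths["x"] == pytest.approx(3.0, abs=1e-12)
        assert prof.strengths["y"] == pytest.approx(3.0, abs=1e-12)
        assert prof.strengths["z"] == pytest.approx(1.0, abs=1e-12)
        assert prof.probabilities["x"] == pytest.approx(3 / 7)
        assert prof.probabilities["z"] == pytest.approx(1 / 7)
        assert sum(prof.strengths.values()) == pytest.approx(7.0)

    def test_disconnected_components_walk_independently(self):
        g = load_arg([(0, 1), (1, 2), (10, 11), (11, 12)], {2: "a", 12: "b"})
        prof = walk_profile(g)
        assert prof.strengths == {"a": 2.0, "b": 2.0}

    def test_no_labelled_leaves_errors(self):
        g = load_arg([(0, 1)])
        with pytest.raises(ArgValidationError, match="labelled"):
            walk_profile(g)

    def test_mass_conservation_on_random_dags(self):
        rng = np.random.default_rng(23)
        for _ in range(300):
            g = random_dag(rng, 50, p_edge=0.12)
            w = backward_weights(g)
            prof = forward_walk(g, transition_matrix(w), w)
            init = sum(
                wt for (u, _), wt in w.w.items()
                if not any(e[1] == u for e in g.edges)
            )
            got = sum(prof.strengths.values())
            assert got == pytest.approx(init, rel=1e-9)

    def test_leaf_strengths_match_path_enumeration_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(300):
            g = random_dag(rng, 20)
            prof = walk_profile(g)
            expected = leaf_mass_oracle(list(g.edges), g.leaf_labels)
            for hap, mass in expected.items():
                assert prof.strengths[hap] == pytest.approx(mass, rel=1e-9, abs=1e-12)

    def test_determinism_under_node_relabelling(self):
        edges = [(0, 2), (1, 2), (2, 3), (2, 4), (0, 5)]
        labels = {3: "x", 4: "y", 5: "z"}
        perm = {0: 50, 1: 41, 2: 32, 3: 23, 4: 14, 5: 5}
        g1 = load_arg(edges, labels)
        g2 = load_arg(
            [(perm[u], perm[v]) for u, v in edges],
            {perm[k]: v for k, v in labels.items()},
        )
        assert walk_profile(g1).probabilities == walk_profile(g2).probabilities


def test_profile_tsv_round_trip(tmp_path, six_node_graph):
    prof = walk_profile(six_node_graph, "hs1")
    write_profile(prof, tmp_path / "p.tsv")
    back = read_profile(tmp_path / "p.tsv")
    assert back.hotspot_id == "hs1"
    assert back.strengths == prof.strengths
    assert back.probabilities == prof.probabilities
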