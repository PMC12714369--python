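"""Feed-forward loop enumeration and coherent/incoherent typing."""

import itertools

import numpy as np
import pytest

from pdinet import (
    classify_ffl,
    enumerate_ffls,
    generate_expression,
    generate_network,
    network_from_edges,
    sign_edges,
    significant_ffls,
)
from pdinet.exceptions import DomainError
from pdinet.ffl import COHERENT_TYPES, INCOHERENT_TYPES, SIGN_TYPE_TABLE

from conftest import make_expression


def brute_force_ffls(net):
    """O(n^3) scan over all ordered node triples."""
    pairs = net.edge_pairs
    nodes = sorted(net.nodes)
    found = set()
    for a, b, c in itertools.permutations(nodes, 3):
        if (a, b) in pairs and (a, c) in pairs and (b, c) in pairs:
            found.add((a, b, c))
    return found


class TestEnumeration:
    def test_single_loop(self, ffl_net):
        loops = enumerate_ffls(ffl_net)
        assert [f.triple for f in loops] == [("A", "B", "p")]

    def test_bipartite_network_has_none(self, toy_net):
        assert enumerate_ffls(toy_net) == []

    def test_mutual_tf_pair_gives_four_ordered_loops(self):
        net = network_from_edges(
            [("A", "B"), ("B", "A"), ("A", "p"), ("B", "p"), ("A", "q"), ("B", "q")]
        )
        triples = {f.triple for f in enumerate_ffls(net)}
        assert triples == {("A", "B", "p"), ("B", "A", "p"),
                           ("A", "B", "q"), ("B", "A", "q")}

    def test_unordered_collapses_mirror_pairs(self):
        net = network_from_edges(
            [("A", "B"), ("B", "A"), ("A", "p"), ("B", "p")]
        )
        assert len(enumerate_ffls(net, ordered=True)) == 2
        assert len(enumerate_ffls(net, ordered=False)) == 1

    def test_self_loops_never_participate(self):
        net = network_from_edges([("A", "A"), ("A", "B"), ("B", "A"), ("A", "p"), ("B", "p")])
        for f in enumerate_ffls(net):
            assert len({f.tf1, f.tf2, f.target}) == 3

    def test_matches_brute_force_on_random_networks(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 30))
            density = rng.uniform(0.02, 0.25)
            nodes = [f"n{i}" for i in range(n)]
            edges = [
                (a, b)
                for a in nodes
                for b in nodes
                if a != b and rng.random() < density
            ]
            if not edges:
                continue
            net = network_from_edges(edges)
            got = {f.triple for f in enumerate_ffls(net)}
            assert got == brute_force_ffls(net)

    def test_count_invariant_under_relabeling(self, rng):
        net, _ = generate_network(
            n_tfs=20, n_promoters=15, n_dual_nodes=8, mean_outdegree=3.0, seed=7
        )
        n_before = len(enumerate_ffls(net))
        nodes = sorted(net.nodes)
        perm = dict(zip(nodes, rng.permutation(nodes)))
        shuffled = network_from_edges(
            [(perm[e.tf_id], perm[e.promoter_id]) for e in net.edges]
        )
        assert len(enumerate_ffls(shuffled)) == n_before


class TestClassification:
    def test_all_activation_is_c1(self):
        assert classify_ffl(("+", "+", "+")) == "c1"

    def test_full_table_is_total_and_partitioned(self):
        seen = {}
        for signs in itertools.product("+-", repeat=3):
            seen[signs] = classify_ffl(signs)
        assert sorted(seen.values()) == ["c1", "c2", "c3", "c4", "i1", "i2", "i3", "i4"]
        for (s1, s2, s3), typ in seen.items():
            product = (1 if s1 == "+" else -1) * (1 if s2 == "+" else -1)
            direct = 1 if s3 == "+" else -1
            if product == direct:
                assert typ in COHERENT_TYPES
            else:
                assert typ in INCOHERENT_TYPES

    def test_canonical_incoherent_type_one(self):
        # activation along both edges of the indirect path except a
        # repressive middle step, direct edge activating
        assert classify_ffl(("+", "-", "+")) == "i1"

    def test_undetermined_sign_is_unclassified(self):
        assert classify_ffl(("+", "+", "undetermined")) == "unclassified"

    def test_invalid_token_rejected(self):
        with pytest.raises(DomainError):
            classify_ffl(("+", "0", "-"))

    def test_table_constant_matches_classifier(self):
        for signs, typ in SIGN_TYPE_TABLE.items():
            assert classify_ffl(signs) == typ


class TestSignificantFFLs:
    def _signed_ffl(self, s2_sign=1, s3_sign=1):
        tf1 = np.repeat(np.linspace(1, 10, 6), 3)
        expr = make_expression(
            {"A": tf1, "B": 2 * tf1 + 1,
             "p": 20 + s2_sign * 1.5 * tf1 + s3_sign * 0.5 * tf1}
        )
        net = network_from_edges([("A", "B"), ("A", "p"), ("B", "p")])
        snet = sign_edges(net, expr, "leaf")
        return significant_ffls(snet, enumerate_ffls(net), "leaf")

    def test_all_activating_loop_is_c1(self):
        sig = self._signed_ffl(1, 1)
        assert len(sig.significant) == 1
        assert sig.significant[0].ffl_type == "c1"
        assert sig.type_counts == {"c1": 1}

    def test_weak_edge_drops_loop_to_unclassified(self):
        tf1 = np.repeat(np.linspace(1, 10, 6), 3)
        scrambled = np.repeat([4, 9, 1, 7, 2, 6.0], 3)
        expr = make_expression({"A": tf1, "B": 2 * tf1, "p": scrambled})
        net = network_from_edges([("A", "B"), ("A", "p"), ("B", "p")])
        snet = sign_edges(net, expr, "leaf")
        sig = significant_ffls(snet, enumerate_ffls(net), "leaf")
        assert sig.significant == []
        assert len(sig.unclassified) == 1

    def test_planted_c2_loop_recovered(self):
        # signs (-, +, -): tf1 represses tf2, tf2 activates target,
        # tf1 represses target
        tf1 = np.repeat(np.linspace(1, 10, 6), 3)
        tf2 = 22 - 2 * tf1
        expr = make_expression({"A": tf1, "B": tf2, "p": 1.2 * tf2 + 3})
        net = network_from_edges([("A", "B"), ("A", "p"), ("B", "p")])
        snet = sign_edges(net, expr, "leaf")
        sig = significant_ffls(snet, enumerate_ffls(net), "leaf")
        assert len(sig.significant) == 1
        assert sig.significant[0].ffl_type == "c2"

    def test_missing_context_raises(self):
        net = network_from_edges([("A", "B"), ("A", "p"), ("B", "p")])
        from pdinet.gini import SignedNetwork

        snet = SignedNetwork(base=net)
        with pytest.raises(DomainError):
            significant_ffls(snet, enumerate_ffls(net), "leaf")


class TestEndToEnd:
    def test_planted_ffl_types_recovered_through_pipeline(self):
        net, truth = generate_network(
            n_tfs=100, n_promoters=300, n_dual_nodes=40, mean_outdegree=1.0,
            hub_fraction=0.0, sign_mode="consistent", n_planted_ffls=25, seed=3,
        )
        expr = generate_expression(net, truth, noise_sigma=0.05, seed=4)
        snet = sign_edges(net, expr, "root")
        sig = significant_ffls(snet, enumerate_ffls(net), "root")
        planted = dict(truth.planted_ffls)
        got = {f.triple: f.ffl_type for f in sig.significant}
        assert len(planted) >= 25
        assert set(planted.values()) <= COHERENT_TYPES
        matches = sum(got.get(t) == typ for t, typ in planted.items())
        assert matches / len(planted) >= 0.90
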