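"""Determinism and closure properties of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from pdinet import (
    deg_status,
    enumerate_ffls,
    generate_deg_table,
    generate_expression,
    generate_network,
    generate_ortholog_pair,
)
from pdinet.exceptions import DomainError
from pdinet.ffl import COHERENT_TYPES


class TestGenerateNetwork:
    def test_same_seed_identical_networks(self):
        a, ta = generate_network(n_tfs=50, n_promoters=30, n_dual_nodes=10,
                                 mean_outdegree=5.0, hub_fraction=0.1, seed=7)
        b, tb = generate_network(n_tfs=50, n_promoters=30, n_dual_nodes=10,
                                 mean_outdegree=5.0, hub_fraction=0.1, seed=7)
        assert a.edge_pairs == b.edge_pairs
        assert ta.planted_edge_signs == tb.planted_edge_signs

    def test_hubs_raise_outdegree_variance(self):
        from pdinet import degree_table

        flat, _ = generate_network(n_tfs=80, n_promoters=60, n_dual_nodes=0,
                                   mean_outdegree=4.0, hub_fraction=0.0, seed=9)
        hubbed, _ = generate_network(n_tfs=80, n_promoters=60, n_dual_nodes=0,
                                     mean_outdegree=4.0, hub_fraction=0.15, seed=9)
        var_flat = degree_table(flat).query("outdegree > 0")["outdegree"].var()
        var_hub = degree_table(hubbed).query("outdegree > 0")["outdegree"].var()
        assert var_hub > var_flat

    def test_no_dual_nodes_means_no_ffls(self):
        net, _ = generate_network(n_tfs=30, n_promoters=20, n_dual_nodes=0,
                                  mean_outdegree=3.0, seed=1)
        assert enumerate_ffls(net) == []

    def test_impossible_outdegree_rejected(self):
        with pytest.raises(DomainError):
            generate_network(n_tfs=10, n_promoters=3, n_dual_nodes=0,
                             mean_outdegree=50.0)

    def test_consistent_sign_mode_plants_only_coherent_loops(self):
        net, truth = generate_network(n_tfs=40, n_promoters=30, n_dual_nodes=15,
                                      mean_outdegree=3.0, sign_mode="consistent",
                                      seed=2)
        assert truth.planted_ffls  # loops exist
        assert {typ for _, typ in truth.planted_ffls} <= COHERENT_TYPES

    def test_planted_ffls_match_enumeration(self):
        net, truth = generate_network(n_tfs=40, n_promoters=30, n_dual_nodes=15,
                                      mean_outdegree=3.0, seed=4)
        assert {t for t, _ in truth.planted_ffls} == {
            f.triple for f in enumerate_ffls(net)
        }

    def test_every_edge_has_a_planted_sign(self):
        net, truth = generate_network(n_tfs=20, n_promoters=15, n_dual_nodes=5,
                                      mean_outdegree=2.0, seed=6)
        assert set(truth.planted_edge_signs) == net.edge_pairs
        assert set(truth.planted_edge_signs.values()) <= {"+", "-"}


class TestGenerateExpression:
    def test_same_seed_identical_matrices(self):
        net, truth = generate_network(n_tfs=15, n_promoters=10, n_dual_nodes=3,
                                      mean_outdegree=2.0, seed=5)
        a = generate_expression(net, truth, seed=8)
        b = generate_expression(net, truth, seed=8)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_design_layout_and_nonnegativity(self):
        net, truth = generate_network(n_tfs=10, n_promoters=8, n_dual_nodes=2,
                                      mean_outdegree=2.0, seed=5)
        expr = generate_expression(net, truth, seed=8)
        # 2 tissues x 6 time points x 3 replicates
        assert expr.values.shape == (len(net.nodes), 36)
        assert (expr.values.to_numpy() >= 0).all()
        assert set(expr.meta["phase"]) == {"baseline", "deprivation", "recovery"}
        assert (expr.meta.loc[expr.meta["phase"] == "recovery", "time_h"] > 24).all()

    def test_noiseless_single_regulator_signs_fully_recovered(self):
        from pdinet import sign_edges

        net, truth = generate_network(n_tfs=40, n_promoters=200, n_dual_nodes=0,
                                      mean_outdegree=1.0, hub_fraction=0.0,
                                      frac_negative=0.5, seed=13)
        expr = generate_expression(net, truth, noise_sigma=0.0, seed=14)
        snet = sign_edges(net, expr, "leaf")
        want = {"+": "activating", "-": "repressing"}
        indegree = net.in_neighbors()
        single = [
            e for e in snet.edges_for("leaf") if len(indegree[e.promoter_id]) == 1
        ]
        assert len(single) >= 30
        assert all(
            e.polarity == want[truth.planted_edge_signs[(e.tf_id, e.promoter_id)]]
            for e in single
        )

    def test_invalid_replicates_rejected(self):
        net, truth = generate_network(n_tfs=5, n_promoters=5, n_dual_nodes=0,
                                      mean_outdegree=1.0, seed=0)
        with pytest.raises(DomainError):
            generate_expression(net, truth, n_replicates=0)


class TestGenerateDegTable:
    def test_rates_recovered_binomially(self):
        net, _ = generate_network(n_tfs=500, n_promoters=500, n_dual_nodes=0,
                                  mean_outdegree=1.0, seed=21)
        degs = generate_deg_table(net, tissues=("leaf",), time_points=(3.0,),
                                  frac_up=0.2, frac_down=0.1, seed=22)
        n = len(degs)
        statuses = degs.apply(
            lambda r: deg_status(r["log2fc"], r["padj"]), axis=1
        ).value_counts()
        assert statuses.get("up", 0) == pytest.approx(0.2 * n, abs=3 * np.sqrt(n * 0.2 * 0.8))
        assert statuses.get("down", 0) == pytest.approx(0.1 * n, abs=3 * np.sqrt(n * 0.1 * 0.9))

    def test_zero_rates_give_all_not_de(self):
        net, _ = generate_network(n_tfs=20, n_promoters=20, n_dual_nodes=0,
                                  mean_outdegree=1.0, seed=23)
        degs = generate_deg_table(net, frac_up=0.0, frac_down=0.0, seed=24)
        assert (
            degs.apply(lambda r: deg_status(r["log2fc"], r["padj"]), axis=1) == "not_de"
        ).all()

    def test_rate_overflow_rejected(self):
        net, _ = generate_network(n_tfs=5, n_promoters=5, n_dual_nodes=0,
                                  mean_outdegree=1.0, seed=0)
        with pytest.raises(DomainError):
            generate_deg_table(net, frac_up=0.7, frac_down=0.5)


class TestGenerateOrthologPair:
    def test_full_conservation(self):
        from pdinet import conserved_edges

        net, _ = generate_network(n_tfs=30, n_promoters=20, n_dual_nodes=5,
                                  mean_outdegree=2.0, seed=31)
        net_b, omap, _ = generate_ortholog_pair(
            net, conservation_fraction=1.0, noise_edge_rate=0.0, seed=32
        )
        rep = conserved_edges(net, net_b, omap)
        assert rep.fraction_a == 1.0

    def test_zero_conservation(self):
        from pdinet import conserved_edges

        net, _ = generate_network(n_tfs=30, n_promoters=20, n_dual_nodes=5,
                                  mean_outdegree=2.0, seed=31)
        net_b, omap, _ = generate_ortholog_pair(
            net, conservation_fraction=0.0, seed=33
        )
        rep = conserved_edges(net, net_b, omap)
        assert rep.conserved_a == 0

    def test_generated_networks_pass_validation(self):
        net, truth = generate_network(n_tfs=25, n_promoters=20, n_dual_nodes=5,
                                      mean_outdegree=3.0, seed=35)
        net_b, omap, _ = generate_ortholog_pair(net, seed=36)
        net.validate()
        net_b.validate()
        expr = generate_expression(net, truth, seed=37)
        expr.validate()

    def test_truth_serializes_to_json(self):
        import json

        net, truth = generate_network(n_tfs=10, n_promoters=8, n_dual_nodes=3,
                                      mean_outdegree=2.0, seed=38)
        payload = json.loads(truth.to_json())
        assert payload["seed"] == 38
        assert len(payload["planted_edge_signs"]) == net.n_edges
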