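"""Node- and network-level statistics against examples and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_network, random_digraph
from _oracles import (
    oracle_betweenness_raw,
    oracle_closeness_std,
    oracle_local_clustering,
)

from transfernet import (
    Hospital,
    betweenness,
    closeness,
    compute_node_metrics,
    degree_distribution,
    degree_metrics,
    degree_population_regression,
    distributor_discharge_comparison,
    in_degree_centralization,
    local_clustering,
    network_metrics,
    node_metrics_frame,
    two_proportion_ztest,
)

PATH_ABC = {("A", "B"): 1, ("B", "C"): 1}


def inward_star(n):
    return make_network({(f"s{i}", "hub"): 1 for i in range(1, n)})


class TestDegrees:
    def test_star_hub_degrees_and_net_connectivity(self):
        nodes = {m.hospital_id: m for m in degree_metrics(inward_star(6))}
        hub = nodes["hub"]
        assert (hub.in_degree, hub.out_degree, hub.net_connectivity) == (5, 0, 5)
        assert all(
            (m.in_degree, m.out_degree) == (0, 1)
            for v, m in nodes.items() if v != "hub"
        )

    def test_degrees_ignore_arc_weights(self):
        m = {x.hospital_id: x for x in degree_metrics(make_network({("A", "B"): 100}))}
        assert m["A"].out_degree == 1 and m["B"].in_degree == 1

    def test_degree_sums_equal_arc_count(self, default_net):
        nodes = degree_metrics(default_net)
        assert sum(m.in_degree for m in nodes) == default_net.n_arcs
        assert sum(m.out_degree for m in nodes) == default_net.n_arcs

    def test_planted_high_in_degree_hubs_are_recovered(self):
        """16 designated hubs given >= 15 in-partners by construction are
        exactly the hospitals with in_degree >= 15."""
        arcs = {}
        hubs = [f"hub{i}" for i in range(16)]
        spokes = [f"sp{i}" for i in range(40)]
        rng = np.random.default_rng(3)
        for h in hubs:
            for s in rng.choice(spokes, size=int(rng.integers(15, 25)),
                                replace=False):
                arcs[(s, h)] = 1
        for i, s in enumerate(spokes):  # sprinkle low-degree noise
            arcs[(s, spokes[(i + 1) % len(spokes)])] = 1
        nodes = degree_metrics(make_network(arcs))
        assert {m.hospital_id for m in nodes if m.in_degree >= 15} == set(hubs)


class TestBetweenness:
    def test_single_intermediary_on_directed_path(self):
        net = make_network(PATH_ABC)
        raw = betweenness(net, standardized=False)
        assert raw == {"A": 0.0, "B": 1.0, "C": 0.0}
        assert betweenness(net)["B"] == pytest.approx(0.5)

    def test_complete_digraph_has_zero_betweenness(self):
        ids = list("ABCD")
        net = make_network({(a, b): 1 for a in ids for b in ids if a != b})
        assert all(v == 0.0 for v in betweenness(net).values())

    def test_fractional_credit_splits_over_parallel_geodesics(self):
        net = make_network(
            {("s", "m1"): 1, ("s", "m2"): 1, ("m1", "t"): 1, ("m2", "t"): 1}
        )
        raw = betweenness(net, standardized=False)
        assert raw["m1"] == pytest.approx(0.5) and raw["m2"] == pytest.approx(0.5)

    def test_standardization_needs_three_nodes(self):
        with pytest.raises(ValueError):
            betweenness(make_network({("A", "B"): 1}))

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_path_enumeration_oracle(self, seed):
        net = random_digraph(seed, n_min=4, n_max=9)
        raw = betweenness(net, standardized=False)
        oracle = oracle_betweenness_raw(net)
        for v in net.nodes:
            assert raw[v] == pytest.approx(oracle[v], abs=1e-9)


class TestCloseness:
    def test_directed_path_out_closeness(self):
        cl = closeness(make_network(PATH_ABC), direction="out")
        assert cl["A"] == pytest.approx(2 / 3)
        # B reaches only C; unreachable A counts as distance N=3
        assert cl["B"] == pytest.approx(2 / 4)
        assert cl["C"] == 0.0

    def test_isolate_scores_zero_under_both_conventions(self):
        net = make_network({("A", "B"): 1}, extra_nodes=["Z"])
        for conv in ("penalize", "reachable_only"):
            assert closeness(net, unreachable=conv)["Z"] == 0.0

    def test_in_direction_reverses_flows(self):
        cl = closeness(make_network(PATH_ABC), direction="in")
        assert cl["C"] == pytest.approx(2 / 3)
        assert cl["A"] == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(
        seed=st.integers(0, 100_000),
        direction=st.sampled_from(["out", "in"]),
        conv=st.sampled_from(["penalize", "reachable_only"]),
    )
    def test_matches_bfs_oracle(self, seed, direction, conv):
        net = random_digraph(seed, n_min=3, n_max=10)
        ours = closeness(net, direction=direction, unreachable=conv)
        oracle = oracle_closeness_std(net, direction=direction, unreachable=conv)
        for v in net.nodes:
            assert ours[v] == pytest.approx(oracle[v], abs=1e-9)


class TestClustering:
    def test_fully_mutual_triangle_is_one(self):
        ids = list("ABC")
        net = make_network({(a, b): 1 for a in ids for b in ids if a != b})
        assert all(v == 1.0 for v in local_clustering(net).values())

    def test_star_hub_with_unconnected_spokes_is_zero(self):
        assert local_clustering(inward_star(6))["hub"] == 0.0

    def test_fewer_than_two_neighbors_scores_zero(self):
        assert local_clustering(make_network({("A", "B"): 1}))["A"] == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_matches_neighbor_enumeration_oracle(self, seed):
        net = random_digraph(seed, n_min=3, n_max=10)
        ours = local_clustering(net)
        oracle = oracle_local_clustering(net)
        for v in net.nodes:
            assert ours[v] == pytest.approx(oracle[v], abs=1e-9)


class TestNetworkMetrics:
    def test_inward_star_centralization_is_exactly_one(self):
        for n in (5, 20, 60):
            assert in_degree_centralization(inward_star(n)) == 1.0

    def test_regular_digraph_centralization_is_exactly_zero(self):
        ids = [f"v{i}" for i in range(7)]
        cycle = make_network(
            {(ids[i], ids[(i + 1) % 7]): 1 for i in range(7)}
        )
        assert in_degree_centralization(cycle) == 0.0

    def test_density_and_reciprocity_formulas(self):
        net = make_network({("A", "B"): 1, ("B", "A"): 1, ("A", "C"): 1})
        m = network_metrics(net)
        assert m.density == pytest.approx(3 / 6)
        assert m.reciprocity == pytest.approx(1 / 2)
        assert m.census.n_arcs == net.n_arcs

    def test_too_small_networks_are_rejected(self):
        with pytest.raises(ValueError):
            network_metrics(make_network({}, extra_nodes=["A"]))

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_all_standardized_metrics_lie_in_unit_interval(self, seed):
        net = random_digraph(seed, n_min=3, n_max=10)
        m = network_metrics(net)
        for value in (m.density, m.in_degree_centralization, m.avg_clustering):
            assert 0.0 <= value <= 1.0
        if m.reciprocity == m.reciprocity:
            assert 0.0 <= m.reciprocity <= 1.0
        for nm in compute_node_metrics(net):
            assert 0.0 <= nm.betweenness_std <= 1.0
            assert 0.0 <= nm.closeness_std <= 1.0
            assert 0.0 <= nm.clustering_local <= 1.0

    def test_skeleton_density_never_exceeds_overall(self, default_net):
        from transfernet import extract_skeleton

        m0 = network_metrics(default_net)
        for cut in (5, 36, 100):
            sk = extract_skeleton(default_net, cut)
            if sk.n_nodes >= 2:
                assert network_metrics(sk).n_nodes <= m0.n_nodes


class TestRegression:
    def _nodes(self, degs):
        return [
            type("NM", (), {"hospital_id": f"h{i}", "in_degree": d})()
            for i, d in enumerate(degs)
        ]

    def _registry(self, pops):
        return [
            Hospital(f"h{i}", population_served=p * 1e6, longitude=0, latitude=0)
            for i, p in enumerate(pops)
        ]

    def test_exact_line_is_recovered(self):
        fit = degree_population_regression(
            self._nodes([5, 10, 15]), self._registry([1, 2, 3])
        )
        assert fit.slope == pytest.approx(5.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_constant_in_degree_gives_zero_slope(self):
        fit = degree_population_regression(
            self._nodes([4, 4, 4, 4]), self._registry([1, 2, 3, 4])
        )
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_zero_population_variance_is_an_error(self):
        with pytest.raises(ValueError):
            degree_population_regression(
                self._nodes([1, 2, 3]), self._registry([2, 2, 2])
            )

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            degree_population_regression(
                self._nodes([1, 2]), self._registry([1, 2])
            )


class TestDistributorComparison:
    def _records(self, senders, dispositions):
        return pd.DataFrame(
            {
                "record_id": [f"r{i}" for i in range(len(senders))],
                "sender_id": senders,
                "receiver_id": "X",
                "disposition": dispositions,
            }
        )

    def test_printed_style_percentages(self):
        # distributor sender D: 62/1000 discharged; others 54/1000
        senders = ["D"] * 1000 + ["O"] * 1000
        disp = (
            ["discharged_outpatient"] * 62 + ["ward_admission"] * 938
            + ["discharged_outpatient"] * 54 + ["ward_admission"] * 946
        )
        net = make_network(
            {("D", "X"): 1, ("D", "Y"): 1, ("O", "X"): 1, ("X", "O"): 1,
             ("Y", "O"): 1}
        )
        cmp = distributor_discharge_comparison(
            self._records(senders, disp), degree_metrics(net), quantile=0.3
        )
        assert (cmp.percent_a, cmp.percent_b) == (6.2, 5.4)
        assert cmp.group_a_hospitals == ["D"]

    def test_identical_groups_give_p_value_one(self):
        assert two_proportion_ztest(50, 1000, 50, 1000) == pytest.approx(1.0)

    def test_injected_difference_detected_with_correct_sign(self, default_sim,
                                                            default_net):
        _, _, records, ledger = default_sim
        cmp = distributor_discharge_comparison(
            records, degree_metrics(default_net), quantile=0.05
        )
        assert set(cmp.group_a_hospitals) == set(ledger.planted_distributor_ids)
        assert cmp.percent_a > cmp.percent_b

    def test_empty_group_is_an_error(self):
        net = make_network({("D", "X"): 1})
        with pytest.raises(ValueError):
            distributor_discharge_comparison(
                self._records(["D"], ["ward_admission"]),
                degree_metrics(net),
            )


class TestDegreeDistribution:
    def test_median_of_small_sample(self):
        nodes = [
            type("NM", (), {"in_degree": d, "out_degree": d, "total_degree": d})()
            for d in (1, 2, 2, 9)
        ]
        dist = degree_distribution(nodes, "in")
        assert dist.median == 2.0
        assert dict(dist.histogram) == {1: 1, 2: 2, 9: 1}

    def test_single_isolated_node(self):
        nodes = degree_metrics(make_network({}, extra_nodes=["A"]))
        assert degree_distribution(nodes, "in").histogram == [(0, 1)]

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            degree_distribution([], "sideways")


def test_node_metrics_frame_column_order(default_net):
    df = node_metrics_frame(compute_node_metrics(default_net))
    assert list(df.columns)[:4] == [
        "hospital_id", "in_degree", "out_degree", "total_degree"
    ]
    assert len(df) == default_net.n_nodes
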