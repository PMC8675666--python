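import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssgnet.events import filter_shots, segment_possessions
from ssgnet.networks import (PageRankParams, PassingNetwork,
                             betweenness_centrality, build_network,
                             centrality_table, closeness_centrality,
                             degree_centralities, degree_centrality,
                             network_density, network_intensity, page_rank,
                             page_rank_linear, shortest_paths)
from .conftest import PLAYERS_A
from .oracles import brute_betweenness, brute_closeness, brute_paths

P = PLAYERS_A


def net_from_adj(a, T=2.0):
    return PassingNetwork(node_ids=P[:a.shape[0]], w=np.asarray(a, float),
                          possession_time_min=T)


def cycle4():
    a = np.zeros((4, 4))
    for i in range(4):
        a[i, (i + 1) % 4] = 1
    return net_from_adj(a)


def star_bidirectional(hub=0):
    a = np.zeros((4, 4))
    for leaf in range(4):
        if leaf != hub:
            a[hub, leaf] = a[leaf, hub] = 1
    return net_from_adj(a)


def complete4():
    return net_from_adj(np.ones((4, 4)) - np.eye(4))


class TestBuildNetwork:
    def test_counts_weights(self, simple_dataset):
        ev = filter_shots(simple_dataset.events)
        succ = ev.loc[(ev["team_id"] == "TA") & ev["success"]]
        poss = segment_possessions(ev, simple_dataset.games.iloc[0])
        net = build_network(succ, poss.loc[poss["team_id"] == "TA"], P)
        assert net.w[0, 1] == 1  # A1 -> A2
        assert net.w[1, 2] == 1  # A2 -> A3
        assert net.w[3, 0] == 1  # A4 -> A1
        assert net.total_passes == 3
        # TA possessions: (2->11) + (20->20) = 9 s
        assert net.possession_time_min == pytest.approx(9.0 / 60.0)

    def test_repeated_pass_accumulates(self):
        ev = pd.DataFrame({
            "game_id": "G1", "time_s": [1.0, 2.0, 3.0], "team_id": "TA",
            "passer_id": ["A1", "A1", "A2"],
            "receiver_id": ["A2", "A2", "A3"],
            "success": True, "is_shot": False})
        net = build_network(ev, pd.DataFrame(columns=["start_s", "end_s"]), P)
        assert net.w[0, 1] == 2 and net.w[1, 2] == 1
        assert net.w.sum() == 3

    def test_empty_gives_zero_matrices(self):
        net = build_network(pd.DataFrame(columns=["passer_id", "receiver_id",
                                                  "success"]),
                            pd.DataFrame(columns=["start_s", "end_s"]), P)
        assert net.w.sum() == 0 and net.a.sum() == 0

    def test_outside_roster_rejected(self):
        ev = pd.DataFrame({"game_id": "G1", "time_s": [1.0], "team_id": "TA",
                           "passer_id": ["B1"], "receiver_id": ["A2"],
                           "success": True, "is_shot": False})
        with pytest.raises(ValueError, match="B1"):
            build_network(ev, pd.DataFrame(columns=["start_s", "end_s"]), P)


class TestMacroMetrics:
    def test_density_complete(self):
        assert network_density(complete4()) == 1.0

    def test_density_partial(self):
        a = np.ones((4, 4)) - np.eye(4)
        a[0, 1] = a[1, 0] = a[2, 3] = 0  # 9 of 12 options used
        assert network_density(net_from_adj(a)) == pytest.approx(0.75)

    def test_density_empty(self):
        assert network_density(net_from_adj(np.zeros((4, 4)))) == 0.0

    def test_density_single_node_undefined(self):
        with pytest.raises(ValueError):
            network_density(PassingNetwork(["A1"], np.zeros((1, 1)), 1.0))

    def test_intensity_passes_per_minute(self):
        net = PassingNetwork(P, np.diag([0.0] * 4), 2.5)
        net.w[0, 1] = 6
        net.w[1, 2] = 4
        assert network_intensity(net) == pytest.approx(4.0)

    def test_intensity_scale_invariance(self):
        w = np.zeros((4, 4))
        w[0, 1] = 9
        one = PassingNetwork(P, w, 2.0)
        two = PassingNetwork(P, 2 * w, 4.0)
        assert network_intensity(one) == pytest.approx(4.5)
        assert network_intensity(two) == pytest.approx(network_intensity(one))

    def test_intensity_zero_time(self):
        w = np.zeros((4, 4))
        with pytest.warns(UserWarning):
            assert network_intensity(PassingNetwork(P, w, 0.0)) == 0.0
        w[0, 1] = 1
        with pytest.raises(ValueError):
            network_intensity(PassingNetwork(P, w, 0.0))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_intensity_halves_when_time_doubles(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.integers(0, 5, (4, 4)).astype(float)
        np.fill_diagonal(w, 0)
        if w.sum() == 0:
            w[0, 1] = 1
        base = network_intensity(PassingNetwork(P, w, 2.0))
        assert network_intensity(PassingNetwork(P, w, 4.0)) == \
            pytest.approx(base / 2)


class TestDegree:
    def test_made_plus_received(self):
        w = np.zeros((4, 4))
        w[0, 1] = 3; w[0, 2] = 2; w[2, 0] = 4  # A1 makes 5, receives 4
        net = net_from_adj(w)
        assert degree_centrality(net, "A1") == 9

    def test_isolated_player_zero(self):
        w = np.zeros((4, 4)); w[1, 2] = 5
        assert degree_centrality(net_from_adj(w), "A1") == 0

    def test_unknown_player_key_error(self):
        with pytest.raises(KeyError):
            degree_centrality(complete4(), "nobody")

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_handshake_identity(self, seed):
        """Sum of degrees equals twice the total pass count."""
        rng = np.random.default_rng(seed)
        w = rng.integers(0, 6, (4, 4)).astype(float)
        np.fill_diagonal(w, 0)
        net = net_from_adj(w)
        assert degree_centralities(net).sum() == pytest.approx(2 * w.sum())


class TestShortestPaths:
    def test_directed_cycle_distances(self):
        paths = shortest_paths(cycle4())
        assert list(paths.dist[0, :]) == [0, 1, 2, 3]
        assert paths.sigma[0, 3] == 1

    def test_star_leaf_to_leaf(self):
        paths = shortest_paths(star_bidirectional(hub=0))
        assert paths.dist[1, 2] == 2
        assert paths.sigma[1, 2] == 1
        assert paths.sigma_through[0][1, 2] == 1

    def test_no_edges(self):
        paths = shortest_paths(net_from_adj(np.zeros((4, 4))))
        off = ~np.eye(4, dtype=bool)
        assert np.all(np.isinf(paths.dist[off]))
        assert paths.sigma[off].sum() == 0

    def test_inverse_weight_prefers_strong_links(self):
        # A1->A2 used 4 times (length .25) vs direct A1->A3 once (length 1):
        # the two-hop route through A2 is shorter under inverse weighting
        w = np.zeros((4, 4))
        w[0, 1] = 4; w[1, 2] = 4; w[0, 2] = 1; w[2, 3] = 1
        net = net_from_adj(w)
        hops = shortest_paths(net, weighting="hops")
        inv = shortest_paths(net, weighting="inverse-weight")
        assert hops.dist[0, 2] == 1
        assert inv.dist[0, 2] == pytest.approx(0.5)


class TestCentralitiesAgainstOracles:
    def test_cycle_closeness(self):
        paths = shortest_paths(cycle4())
        for i in range(4):
            assert closeness_centrality(paths, i) == pytest.approx(1 / 6)

    def test_star_hub_closeness(self):
        paths = shortest_paths(star_bidirectional())
        assert closeness_centrality(paths, 0) == pytest.approx(1 / 3)
        assert closeness_centrality(paths, 1) == pytest.approx(1 / 5)

    def test_sink_player_zero_closeness(self):
        a = np.zeros((4, 4)); a[1, 0] = 1  # node 0 has no out-edges
        paths = shortest_paths(net_from_adj(a))
        assert closeness_centrality(paths, 0) == 0.0

    def test_star_hub_betweenness(self):
        paths = shortest_paths(star_bidirectional())
        assert betweenness_centrality(paths, 0) == pytest.approx(6.0)
        for leaf in (1, 2, 3):
            assert betweenness_centrality(paths, leaf) == 0.0

    def test_complete_graph_betweenness_zero(self):
        paths = shortest_paths(complete4())
        for i in range(4):
            assert betweenness_centrality(paths, i) == 0.0

    @given(st.integers(0, 2**12 - 1))
    @settings(max_examples=120, deadline=None)
    def test_random_4node_digraphs_match_brute_force(self, code):
        from .oracles import int_to_digraph
        a = int_to_digraph(code)
        net = net_from_adj(a.astype(float))
        paths = shortest_paths(net)
        bdist, bsigma, _ = brute_paths(a)
        assert np.array_equal(np.nan_to_num(paths.dist, posinf=-1),
                              np.nan_to_num(bdist, posinf=-1))
        assert np.array_equal(paths.sigma, bsigma)
        for i in range(4):
            assert closeness_centrality(paths, i) == \
                pytest.approx(brute_closeness(a, i))
            assert betweenness_centrality(paths, i) == \
                pytest.approx(brute_betweenness(a, i))


class TestPageRank:
    def test_complete_symmetric_uniform(self):
        pr = page_rank(complete4())
        assert pr == pytest.approx([0.25] * 4)

    def test_zero_damping_uniform(self):
        pr = page_rank(cycle4(), PageRankParams(d=0.0))
        assert pr == pytest.approx([0.25] * 4)

    def test_no_inedge_node_closed_form(self):
        # x feeds a 3-cycle; no dangling nodes, so PR(x) = (1-d)/N
        a = np.zeros((4, 4))
        a[0, 1] = 1; a[1, 2] = 1; a[2, 3] = 1; a[3, 1] = 1
        pr = page_rank(net_from_adj(a), PageRankParams(d=0.85))
        assert pr[0] == pytest.approx(0.15 / 4)

    def test_sums_to_one_and_matches_linear_solve(self, rng):
        for _ in range(25):
            a = (rng.random((4, 4)) < 0.4).astype(float)
            np.fill_diagonal(a, 0)
            net = net_from_adj(a)
            pr = page_rank(net)
            assert pr.sum() == pytest.approx(1.0, abs=1e-8)
            assert pr == pytest.approx(page_rank_linear(net), abs=1e-8)

    def test_matches_networkx(self, rng):
        nx = pytest.importorskip("networkx")
        for _ in range(25):
            a = (rng.random((5, 5)) < 0.35).astype(float)
            np.fill_diagonal(a, 0)
            net = PassingNetwork([f"P{i}" for i in range(5)], a, 1.0)
            g = nx.from_numpy_array(a, create_using=nx.DiGraph)
            ref = nx.pagerank(g, alpha=0.85, tol=1e-12, max_iter=2000)
            pr = page_rank(net, PageRankParams(tol=1e-12))
            assert pr == pytest.approx([ref[i] for i in range(5)], abs=1e-8)

    def test_nonconvergence_raises(self):
        a = np.zeros((4, 4))
        a[0, 1] = 1; a[1, 2] = 1; a[2, 3] = 1; a[3, 0] = 1; a[0, 2] = 1
        with pytest.raises(RuntimeError, match="converge"):
            page_rank(net_from_adj(a), PageRankParams(tol=1e-15, max_iter=2))


class TestCentralityTable:
    def test_pagerank_column_sums_to_one(self, rng):
        a = (rng.random((4, 4)) < 0.5).astype(float)
        np.fill_diagonal(a, 0)
        tab = centrality_table(net_from_adj(a))
        assert tab["pagerank"].sum() == pytest.approx(1.0, abs=1e-8)
        assert (tab[["degree", "closeness", "betweenness", "pagerank"]]
                .ge(0).all().all())
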