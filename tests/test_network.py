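import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dysbiome import (
    AbundanceTable,
    TaxonRecord,
    ValidationError,
    build_network,
    core_interactions,
    critical_r,
    hub_analysis,
    rank_normalize,
    spearman_ties,
    summarize_network,
)
from dysbiome.network import CooccurrenceNetwork, correlation_matrix, edge_table


# --- oracles -----------------------------------------------------------------


def pearson_on_ranks_oracle(x, y):
    """First-principles: means, deviations, sample sds, term-by-term sums."""
    n = len(x)
    xb = sum(x) / n
    yb = sum(y) / n
    sx = math.sqrt(sum((v - xb) ** 2 for v in x) / (n - 1))
    sy = math.sqrt(sum((v - yb) ** 2 for v in y) / (n - 1))
    return sum((a - xb) * (b - yb) for a, b in zip(x, y)) / ((n - 1) * sx * sy)


def bfs_centrality_oracle(g: nx.Graph):
    """Degree and normalized shortest-path betweenness by explicit path
    enumeration (feasible on <= 12 nodes)."""
    nodes = list(g.nodes)
    deg = {n: sum(1 for _ in g.neighbors(n)) for n in nodes}
    bet = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        # all shortest paths via BFS layers
        try:
            dist = nx.shortest_path_length(g, s, t)
        except nx.NetworkXNoPath:
            continue
        paths = [
            p for p in nx.all_simple_paths(g, s, t, cutoff=dist) if len(p) - 1 == dist
        ]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += through / len(paths)
    v = len(nodes)
    scale = 2.0 / ((v - 1) * (v - 2)) if v > 2 else 1.0
    return deg, {n: b * scale for n, b in bet.items()}


def _net_from_graph(g, klass="lesional", r0=0.7):
    for _, _, d in g.edges(data=True):
        d.setdefault("r", 0.9)
        d.setdefault("sign", "positive")
    return CooccurrenceNetwork(g, klass, r0, 0.99)


# --- tests -------------------------------------------------------------------


class TestSpearmanTies:
    def test_self_correlation_is_one(self):
        x = np.array([0.2, 0.4, 0.4, 1.0])
        assert spearman_ties(x, x) == pytest.approx(1.0)

    def test_reversed_untied_is_minus_one(self):
        x = np.array([1, 2, 3, 4, 5]) / 5
        assert spearman_ties(x, x[::-1]) == pytest.approx(-1.0)

    def test_matches_first_principles_oracle_with_ties(self, rng):
        from scipy.stats import rankdata

        for _ in range(200):
            n = rng.integers(4, 15)
            x = rankdata(rng.integers(0, 5, n)) / n
            y = rankdata(rng.integers(0, 5, n)) / n
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            assert spearman_ties(x, y) == pytest.approx(
                pearson_on_ranks_oracle(x, y), abs=1e-12
            )

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.random(8), rng.random(8)
        assert spearman_ties(x, y) == pytest.approx(spearman_ties(y, x))

    def test_zero_variance_signals_undefined(self):
        assert math.isnan(spearman_ties([0.5, 0.5, 0.5], [0.2, 0.4, 0.9]))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValidationError):
            spearman_ties([1, 2], [1, 2])


class TestCriticalR:
    def test_strictly_decreasing_in_n(self):
        vals = [critical_r(n) for n in range(5, 51)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_confidence_to_one_limit(self):
        assert critical_r(10, confidence=0.999999) > 0.97

    def test_t_approx_agrees_with_permutation_null(self):
        t_val = critical_r(20, 0.99, method="t_approx")
        p_val = critical_r(20, 0.99, method="permutation", perm_reps=200_000, seed=3)
        assert t_val == pytest.approx(p_val, abs=0.02)

    def test_small_n_rejected(self):
        with pytest.raises(ValidationError):
            critical_r(3)


class TestBuildNetwork:
    def _table(self, rows, taxa):
        df = pd.DataFrame(
            rows, index=taxa, columns=[f"s{j}" for j in range(rows.shape[1])]
        )
        return AbundanceTable(df, "counts")

    def test_comonotone_pair_gives_single_positive_edge(self):
        base = np.arange(1, 11, dtype=float)
        table = self._table(np.vstack([base, base * 3 + 2]), ["a", "b"])
        net = build_network(rank_normalize(table))
        assert net.graph.number_of_edges() == 1
        d = net.graph.get_edge_data("a", "b")
        assert d["sign"] == "positive" and d["r"] == pytest.approx(1.0)

    def test_antimonotone_pair_gives_negative_edge(self):
        base = np.arange(1, 11, dtype=float)
        table = self._table(np.vstack([base, base[::-1]]), ["a", "b"])
        net = build_network(rank_normalize(table))
        assert net.graph.get_edge_data("a", "b")["sign"] == "negative"

    def test_constant_taxon_excluded_and_flagged(self):
        base = np.arange(1, 11, dtype=float)
        rows = np.vstack([base, base * 2, np.full(10, 7.0)])
        net = build_network(rank_normalize(self._table(rows, ["a", "b", "flat"])))
        assert net.excluded_taxa == ["flat"]
        assert "flat" not in net.graph

    def test_edge_calling_reproducible(self, rng):
        rows = rng.random((20, 12))
        t = self._table(rows, [f"t{i}" for i in range(20)])
        e1 = build_network(rank_normalize(t)).edges
        e2 = build_network(rank_normalize(t)).edges
        assert e1 == e2

    def test_annotations_attached(self):
        base = np.arange(1, 11, dtype=float)
        table = self._table(np.vstack([base, base * 2]), ["a", "b"])
        ann = {"a": TaxonRecord("a", {"phylum": "Firmicutes"}, {"gram_nature": "positive"})}
        net = build_network(rank_normalize(table), ann)
        assert net.graph.nodes["a"]["phylum"] == "Firmicutes"
        assert net.graph.nodes["a"]["gram_nature"] == "positive"

    def test_no_class_asymmetry_on_identically_distributed_halves(self, rng):
        # same generating distribution for both halves -> edge counts agree
        # within 3 binomial null standard deviations
        n_taxa, n = 60, 20
        pairs = n_taxa * (n_taxa - 1) / 2
        sd3 = 3 * math.sqrt(pairs * 0.01 * 0.99)
        counts = []
        for _ in range(2):
            t = self._table(rng.random((n_taxa, n)), [f"t{i}" for i in range(n_taxa)])
            counts.append(build_network(rank_normalize(t)).graph.number_of_edges())
        assert abs(counts[0] - counts[1]) < 2 * sd3

    def test_too_few_eligible_taxa_rejected(self):
        rows = np.vstack([np.arange(1, 11, dtype=float), np.full(10, 3.0)])
        with pytest.raises(ValidationError):
            build_network(rank_normalize(self._table(rows, ["a", "flat"])))


class TestSummarizeNetwork:
    def test_complete_graph(self):
        s = summarize_network(_net_from_graph(nx.complete_graph(4)))
        assert (s.n_nodes, s.n_edges, s.density, s.diameter) == (4, 6, 1.0, 1)
        assert all(d == 3 for d in s.degree.values())

    def test_path_graph(self):
        s = summarize_network(_net_from_graph(nx.path_graph(4)))
        assert s.diameter == 3
        assert s.betweenness[1] > s.betweenness[0]
        assert s.betweenness[2] > s.betweenness[3]

    def test_matches_path_enumeration_oracle(self, rng):
        g = nx.gnp_random_graph(10, 0.35, seed=5)
        g.remove_nodes_from(list(nx.isolates(g)))
        s = summarize_network(_net_from_graph(g))
        deg, bet = bfs_centrality_oracle(g)
        assert s.degree == deg
        for n in bet:
            assert s.betweenness[n] == pytest.approx(bet[n], abs=1e-9)

    def test_empty_network(self):
        s = summarize_network(_net_from_graph(nx.Graph()))
        assert (s.n_nodes, s.n_edges, s.diameter) == (0, 0, None)


class TestHubAnalysis:
    def test_degree_cutoff_definition(self):
        g = nx.star_graph(10)  # center degree 10, leaves 1
        g.add_edge(1, 2)  # nodes 1,2 now degree 2
        (rep,) = hub_analysis(_net_from_graph(g), thresholds=(80,))
        assert rep.hubs == {0}
        (rep20,) = hub_analysis(_net_from_graph(g), thresholds=(20,))
        assert rep20.hubs == {0, 1, 2}

    def test_threshold_100_keeps_only_max_degree(self):
        g = nx.path_graph(5)
        (rep,) = hub_analysis(_net_from_graph(g), thresholds=(100,))
        assert rep.hubs == {1, 2, 3}  # all middle nodes share max degree 2

    def test_nesting_across_thresholds(self, rng):
        g = nx.gnp_random_graph(25, 0.2, seed=8)
        g.remove_nodes_from(list(nx.isolates(g)))
        reps = hub_analysis(_net_from_graph(g))
        assert reps[3].hubs <= reps[2].hubs <= reps[1].hubs <= reps[0].hubs
        assert all(r.hubs for r in reps)  # max-degree node always qualifies

    def test_composition_matches_group_by_oracle(self):
        g = nx.complete_graph(4)
        phyla = {0: "Firmicutes", 1: "Firmicutes", 2: "Actinobacteria", 3: "TM7"}
        nx.set_node_attributes(g, phyla, "phylum")
        (rep,) = hub_analysis(_net_from_graph(g), thresholds=(60,))
        expect = pd.Series(list(phyla.values())).value_counts().to_dict()
        assert rep.phylum_composition == expect

    def test_edgeless_network_rejected(self):
        with pytest.raises(ValidationError):
            hub_analysis(_net_from_graph(nx.empty_graph(3)))


class TestCoreInteractions:
    def test_identical_networks_share_everything(self):
        g = nx.path_graph(4)
        a, b = _net_from_graph(g.copy()), _net_from_graph(g.copy(), klass="non_lesional")
        assert core_interactions(a, b) == a.edges

    def test_disjoint_edge_sets_share_nothing(self):
        a = _net_from_graph(nx.path_graph([0, 1, 2]))
        b = _net_from_graph(nx.path_graph([3, 4, 5]), klass="non_lesional")
        assert core_interactions(a, b) == set()

    def test_sign_must_match(self):
        ga, gb = nx.Graph(), nx.Graph()
        ga.add_edge("x", "y", r=0.9, sign="positive")
        gb.add_edge("y", "x", r=-0.9, sign="negative")
        assert core_interactions(
            _net_from_graph(ga), _net_from_graph(gb, klass="non_lesional")
        ) == set()

    def test_matches_set_membership_oracle(self, rng):
        def random_net(seed):
            r = np.random.default_rng(seed)
            g = nx.Graph()
            for _ in range(12):
                u, v = r.integers(0, 8, 2)
                if u != v:
                    g.add_edge(int(u), int(v),
                               sign="positive" if r.random() < 0.5 else "negative",
                               r=0.8)
            return _net_from_graph(g)

        a, b = random_net(1), random_net(2)
        expect = {e for e in a.edges if e in b.edges}
        assert core_interactions(a, b) == expect


def test_edge_table_layout():
    g = nx.Graph()
    g.add_edge("b", "a", r=0.9, sign="positive")
    df = edge_table(_net_from_graph(g))
    assert list(df.columns) == ["taxon_a", "taxon_b", "r", "sign"]
    assert df.iloc[0]["taxon_a"] == "a"  # lexicographically ordered pair


def test_correlation_matrix_symmetry_and_diagonal(rng):
    from dysbiome.tables import RankMatrix

    vals = rng.random((8, 10))
    rm = RankMatrix(pd.DataFrame(vals, index=[f"t{i}" for i in range(8)],
                                 columns=[f"s{j}" for j in range(10)]))
    cm = correlation_matrix(rm)
    np.testing.assert_allclose(cm.r, cm.r.T)
    np.testing.assert_allclose(np.diag(cm.r), 1.0)
    assert np.nanmax(np.abs(cm.r)) <= 1.0 + 1e-12
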