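"""Block-model topology: genomic clustering, modularity (against two
independent oracles), edge randomization, Monte-Carlo enrichment against
exact matching enumeration, and nearest-neighbor spacing."""

import itertools

import networkx as nx
import numpy as np
import pytest

import crisischain as cc
from crisischain.topology import BlockModel


class TestClusterBreakends:
    def test_tight_group_is_one_cluster(self, rates):
        records = [cc.make_sv("s", "chr1", 1000 + 10 * i, "T",
                              "chr1", 1000 + 10 * i + 5, "H", "DEL")
                   for i in range(3)]
        chains = cc.detect_chains(records, rates, cc.ChainConfig(t=1e-2, b_min=4))
        labels = cc.cluster_breakends(chains[0], rates, t=1e-2)
        assert set(labels) == {0}

    def test_distant_groups_split(self, rates):
        records = [cc.make_sv("s", "chr1", 1000 + i, "T",
                              "chr1", 40_000_000 + i, "H", "DEL")
                   for i in range(3)]
        chains = cc.detect_chains(records, rates, cc.ChainConfig(t=1e-2, b_min=4))
        labels = cc.cluster_breakends(chains[0], rates, t=1e-2)
        assert len(set(labels)) == 2

    def test_planted_cluster_count_recovered(self, detected_chain, rates):
        labels = cc.cluster_breakends(detected_chain, rates, t=1e-3)
        assert len(set(labels)) == cc.ChainSpec().n_clusters

    def test_empty_chain_errors(self, detected_chain):
        from crisischain.chains import Chain
        empty = Chain("s", [], [], [], [])
        with pytest.raises(ValueError):
            cc.cluster_breakends(empty, cc.BreakRateModel({"chr1": 1e-6}))


class TestBlockModel:
    def test_all_intracluster_gives_diagonal(self, rates):
        records = [cc.make_sv("s", "chr1", 1000 + 10 * i, "T",
                              "chr1", 1000 + 10 * i + 5, "H", "DEL")
                   for i in range(4)]
        (chain,) = cc.detect_chains(records, rates, cc.ChainConfig(t=1e-2, b_min=4))
        labels = cc.cluster_breakends(chain, rates, 1e-2)
        bm = cc.build_block_model(chain, labels)
        assert np.all(bm.adjacency == np.diag(np.diag(bm.adjacency)))
        assert bm.adjacency.trace() == 4

    def test_every_sv_in_exactly_one_cell(self, detected_chain, rates):
        labels = cc.cluster_breakends(detected_chain, rates, 1e-3)
        bm = cc.build_block_model(detected_chain, labels)
        upper = np.triu(bm.adjacency)
        assert upper.sum() == len(detected_chain.sv_edges)
        assert len(bm.edge_labels) == len(detected_chain.sv_edges)
        assert (bm.adjacency == bm.adjacency.T).all()

    def test_homophilic_bias_shows_in_adjacency(self, genome, rates):
        spec = cc.ChainSpec(n_clusters=4, intra_weight=10.0)
        records, _ = cc.plant_chain(genome, spec, seed=23)
        chains = cc.detect_chains(records, rates, cc.ChainConfig(t=1e-3, b_min=6))
        assert chains
        diag = off = 0
        for chain in chains:
            labels = cc.cluster_breakends(chain, rates, 1e-3)
            bm = cc.build_block_model(chain, labels)
            diag += np.diag(bm.adjacency).sum()
            off += np.triu(bm.adjacency, 1).sum()
        assert diag > off

    def test_label_mismatch_errors(self, detected_chain):
        with pytest.raises(ValueError):
            cc.build_block_model(detected_chain, [0, 1])


def brute_force_modularity(adj: np.ndarray, communities: list[int]) -> float:
    """Direct double-sum: Q = sum_ij (A_ij - k_i k_j / 2m) d(c_i, c_j) / 2m
    over the node-level (multi)adjacency matrix."""
    k = adj.sum(axis=1)
    two_m = adj.sum()
    q = 0.0
    n = len(communities)
    for i in range(n):
        for j in range(n):
            if communities[i] == communities[j]:
                q += adj[i, j] - k[i] * k[j] / two_m
    return q / two_m


def _edge_labels_from(adj, communities):
    out = []
    n = len(communities)
    for i in range(n):
        for j in range(i, n):
            reps = adj[i, j] if i != j else adj[i, i] // 2
            out.extend([(min(communities[i], communities[j]),
                         max(communities[i], communities[j]))] * int(reps))
    return out


class TestModularity:
    def test_two_equal_communities_give_half(self):
        assert cc.modularity([(0, 0), (1, 1)]) == pytest.approx(0.5)

    def test_single_community_is_zero(self):
        assert cc.modularity([(0, 0)] * 7) == pytest.approx(0.0)

    def test_no_edges_errors(self):
        with pytest.raises(ValueError):
            cc.modularity([])

    def test_matches_double_sum_on_enumerated_graphs(self):
        # all simple graphs on 4 nodes x all partitions, plus random
        # multigraphs on up to 6 nodes
        rng = np.random.default_rng(31)
        checked = 0
        for n, partitions in ((4, _all_partitions(4)),):
            pairs = list(itertools.combinations(range(n), 2))
            for mask in range(1, 2 ** len(pairs)):
                adj = np.zeros((n, n), dtype=int)
                for b, (i, j) in enumerate(pairs):
                    if mask >> b & 1:
                        adj[i, j] = adj[j, i] = 1
                for communities in partitions:
                    expect = brute_force_modularity(adj, communities)
                    got = cc.modularity(_edge_labels_from(adj, communities))
                    assert got == pytest.approx(expect, abs=1e-12)
                    checked += 1
        for _ in range(300):
            n = int(rng.integers(2, 7))
            adj = rng.integers(0, 3, size=(n, n))
            adj = adj + adj.T
            np.fill_diagonal(adj, 2 * (np.diag(adj) // 2))
            if adj.sum() == 0:
                continue
            communities = rng.integers(0, n, size=n).tolist()
            expect = brute_force_modularity(adj, communities)
            got = cc.modularity(_edge_labels_from(adj, communities))
            assert got == pytest.approx(expect, abs=1e-12)
        assert checked >= 900  # 63 graphs x 15 partitions of 4 nodes

    def test_matches_networkx_on_simple_graphs(self):
        rng = np.random.default_rng(37)
        for _ in range(50):
            g = nx.gnp_random_graph(6, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            communities = rng.integers(0, 3, size=6)
            parts = [set(np.flatnonzero(communities == c)) for c in range(3)]
            parts = [p for p in parts if p]
            expect = nx.community.modularity(g, parts)
            labels = [(min(communities[u], communities[v]),
                       max(communities[u], communities[v])) for u, v in g.edges]
            assert cc.modularity(labels) == pytest.approx(expect, abs=1e-12)


def _all_partitions(n):
    """All set partitions of range(n) as label lists."""
    out = []

    def rec(i, labels, k):
        if i == n:
            out.append(labels.copy())
            return
        for lab in range(k + 1):
            labels.append(lab)
            rec(i + 1, labels, max(k, lab + 1))
            labels.pop()

    rec(0, [], 0)
    return out


class TestRandomizeEdges:
    def test_two_breakends_give_single_edge(self):
        rng = np.random.default_rng(1)
        assert cc.randomize_edges([0, 1], rng) == [(0, 1)]

    def test_edge_count_conserved(self):
        rng = np.random.default_rng(2)
        labels = [0, 0, 1, 1, 2, 2, 0, 1]
        assert len(cc.randomize_edges(labels, rng)) == 4

    def test_odd_count_errors(self):
        with pytest.raises(ValueError):
            cc.randomize_edges([0, 1, 2], np.random.default_rng(3))

    def test_deterministic_under_seed(self):
        labels = [0, 1, 2, 3] * 3
        a = cc.randomize_edges(labels, np.random.default_rng(5))
        b = cc.randomize_edges(labels, np.random.default_rng(5))
        assert a == b

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_intercluster_fraction_matches_matching_enumeration(self, k):
        # 2 clusters of 2k engaged breakends: enumerate all perfect
        # matchings of 4k nodes, count intercluster edges exactly
        labels = [0] * (2 * k) + [1] * (2 * k)
        exact = _expected_cross_fraction(labels)
        rng = np.random.default_rng(7)
        n_sims, total, cross = 4000, 0, 0
        for _ in range(n_sims):
            for ci, cj in cc.randomize_edges(labels, rng):
                total += 1
                cross += ci != cj
        frac = cross / total
        se = np.sqrt(exact * (1 - exact) / n_sims)  # conservative
        assert abs(frac - exact) < 4 * max(se, 0.01)


def _all_matchings(nodes):
    if not nodes:
        yield []
        return
    first, rest = nodes[0], nodes[1:]
    for i, other in enumerate(rest):
        for tail in _all_matchings(rest[:i] + rest[i + 1:]):
            yield [(first, other)] + tail


def _expected_cross_fraction(labels):
    nodes = list(range(len(labels)))
    total = cross = 0
    for matching in _all_matchings(nodes):
        for a, b in matching:
            total += 1
            cross += labels[a] != labels[b]
    return cross / total


class TestModularityComparison:
    def _homophilic_model(self, seed):
        rng = np.random.default_rng(seed)
        edge_labels, node_labels = [], []
        for _ in range(12):
            c = int(rng.integers(4))
            edge_labels.append((c, c))
            node_labels.extend((c, c))
        for _ in range(3):
            i, j = sorted(rng.choice(4, 2, replace=False))
            edge_labels.append((int(i), int(j)))
            node_labels.extend((int(i), int(j)))
        return BlockModel(4, np.zeros((4, 4)), np.zeros(4), edge_labels,
                          node_labels)

    def test_homophilic_chains_beat_randomized(self):
        models = [self._homophilic_model(s) for s in range(6)]
        q_obs, q_rand, p = cc.modularity_comparison(models, n_random=300, seed=8)
        assert (q_obs > q_rand).all()
        assert p < 0.01

    def test_randomized_mean_near_zero(self, detected_chain, rates):
        labels = cc.cluster_breakends(detected_chain, rates, 1e-3)
        bm = cc.build_block_model(detected_chain, labels)
        rng = np.random.default_rng(9)
        qs = [cc.modularity(cc.randomize_edges(bm.node_labels, rng))
              for _ in range(1000)]
        assert abs(np.mean(qs)) < 0.1

    def test_null_rejection_rate_near_alpha(self):
        # chains whose observed pairing is itself a random matching:
        # the paired test should reject at roughly the nominal level
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 60
        for _ in range(reps):
            models = []
            for _ in range(5):
                node_labels = [int(rng.integers(3)) for _ in range(20)]
                edges = cc.randomize_edges(node_labels, rng)
                models.append(BlockModel(3, np.zeros((3, 3)), np.zeros(3),
                                         edges, node_labels))
            _, _, p = cc.modularity_comparison(models, n_random=60,
                                               seed=int(rng.integers(1 << 30)))
            rejections += p < 0.05
        assert rejections / reps < 0.15


class TestEnrichment:
    def _toy_model(self, edge_labels):
        node_labels = [c for e in edge_labels for c in e]
        k = max(node_labels) + 1
        return BlockModel(k, np.zeros((k, k)), np.zeros(k),
                          list(edge_labels), node_labels)

    def test_observed_zero_gives_p_one(self):
        bm = self._toy_model([(0, 0), (1, 1)])
        res = {r.cluster_pair: r for r in cc.intercluster_enrichment(bm, 200, 1)}
        assert res[(0, 1)].observed == 0
        assert res[(0, 1)].p_enriched == 1.0

    def test_floor_at_one_over_nsims_plus_one(self):
        bm = self._toy_model([(0, 1), (0, 1)])
        res = {r.cluster_pair: r for r in cc.intercluster_enrichment(bm, 200, 1)}
        assert res[(0, 1)].p_enriched >= 1 / 201

    def test_nsims_below_100_errors(self):
        with pytest.raises(ValueError):
            cc.intercluster_enrichment(self._toy_model([(0, 1)]), 50, 1)

    def test_matches_exact_matching_enumeration(self):
        # two clusters of two engaged ends each (two SVs, both intercluster):
        # exact null: cross-count 0 w.p. 1/3, 2 w.p. 2/3
        # p_enriched(observed 2) = 1 - P(cross < 2) = 2/3
        bm = self._toy_model([(0, 1), (0, 1)])
        n_sims = 2000
        res = {r.cluster_pair: r
               for r in cc.intercluster_enrichment(bm, n_sims, seed=12)}
        exact = 2 / 3
        se = np.sqrt(exact * (1 - exact) / n_sims)
        assert abs(res[(0, 1)].p_enriched - exact) < 3 * se

    def test_null_pvalues_super_uniform(self):
        rng = np.random.default_rng(13)
        node_labels = [int(rng.integers(3)) for _ in range(16)]
        hits = trials = 0
        for rep in range(40):
            edges = cc.randomize_edges(node_labels, rng)
            k = max(node_labels) + 1
            bm = BlockModel(k, np.zeros((k, k)), np.zeros(k), edges, node_labels)
            for r in cc.intercluster_enrichment(bm, 100, seed=rep):
                trials += 1
                hits += r.p_enriched <= 0.1
        assert hits / trials <= 0.15


class TestSpacing:
    def test_two_points_give_one_distance(self):
        assert cc.nn_distances([100, 250]) == [150]

    def test_equal_spacing_unit_interval_gives_lambda_one(self):
        positions = np.arange(0, 1000, 100)
        fit = cc.nn_rate({"s": [positions]})
        assert fit.lam == pytest.approx(1.0)

    def test_exponential_distances_recover_rate(self):
        rng = np.random.default_rng(14)
        d = rng.exponential(scale=1 / 0.099, size=1000)
        lam = cc.fit_rate(d)
        se = 0.099 / np.sqrt(1000)
        assert abs(lam - 0.099) < 3 * se

    def test_lambda_bias_shrinks_with_n(self):
        rng = np.random.default_rng(15)
        errs = []
        for n in (10, 1000):
            lams = [cc.fit_rate(rng.exponential(2.0, n)) for _ in range(200)]
            errs.append(abs(np.mean(lams) - 0.5))
        assert errs[1] < errs[0]

    def test_no_distances_errors(self):
        with pytest.raises(ValueError):
            cc.nn_rate({"s": [[5]]})


class TestDbFilter:
    def test_strict_bounds(self):
        counts = {"a": 40, "b": 41, "c": 1499, "d": 1500, "e": 6}
        assert cc.db_sample_filter(counts) == ["b", "c"]

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            cc.db_sample_filter({"a": -1})
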