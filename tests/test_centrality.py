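"""Centrality measures against exhaustive small-graph oracles, dynamic series,
and the PCA-based characteristic-centrality ranking."""

import itertools

import numpy as np
import pytest

from microcoh.centrality import (
    ALL_MEASURES,
    characteristic_centrality,
    compute_centrality,
    dynamic_centrality,
)
from microcoh.network_dynamics import DynamicNetwork, Edge, NetworkSnapshot


def snapshot_from_directed(weights: dict, nodes: list) -> NetworkSnapshot:
    """Build a snapshot whose directed view reproduces `weights[(u, v)] = w` (flow u->v)."""
    edges = {}
    for (u, v), w in weights.items():
        if (v, u) in weights and (v, u) not in edges and (u, v) not in edges:
            # reciprocal pairs are not representable by a single signed score; avoid
            raise ValueError("use non-reciprocal fixtures")
        edges[(u, v)] = Edge(weight=w, direction=-1.0, n_bins=1)
    return NetworkSnapshot(nodes=nodes, edges=edges, t_window=None, f_window=None)


def random_digraph(seed: int, n_max: int = 6):
    rng = np.random.default_rng(seed)
    n = rng.integers(3, n_max + 1)
    nodes = [f"n{i}" for i in range(n)]
    weights = {}
    for i, j in itertools.permutations(range(n), 2):
        if i < j and rng.random() < 0.55:
            u, v = (nodes[i], nodes[j]) if rng.random() < 0.5 else (nodes[j], nodes[i])
            weights[(u, v)] = float(rng.uniform(0.1, 1.0))
    return weights, nodes


# --- exhaustive oracles -----------------------------------------------------


def brute_shortest(weights, nodes):
    """All-pairs shortest distances and path counts on 1/weight lengths."""
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for (u, v), w in weights.items():
        dist[idx[u], idx[v]] = 1.0 / w
    for k in range(n):  # Floyd-Warshall
        dist = np.minimum(dist, dist[:, k : k + 1] + dist[k : k + 1, :])
    # path counts: DP over nodes ordered by distance from each source
    counts = np.zeros((n, n))
    adj = {(idx[u], idx[v]): 1.0 / w for (u, v), w in weights.items()}
    for s in range(n):
        counts[s, s] = 1.0
        order = np.argsort(dist[s])
        for v in order:
            if v == s or not np.isfinite(dist[s, v]):
                continue
            c = 0.0
            for u in range(n):
                if (u, v) in adj and np.isclose(dist[s, u] + adj[(u, v)], dist[s, v], atol=1e-12):
                    c += counts[s, u]
            counts[s, v] = c
    return dist, counts


def brute_betweenness(weights, nodes):
    n = len(nodes)
    dist, counts = brute_shortest(weights, nodes)
    bc = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        if not np.isfinite(dist[s, t]) or counts[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if np.isclose(dist[s, v] + dist[v, t], dist[s, t], atol=1e-12):
                bc[v] += counts[s, v] * counts[v, t] / counts[s, t]
    if n > 2:
        bc /= (n - 1) * (n - 2)
    return dict(zip(nodes, bc))


def brute_harmonic_in(weights, nodes):
    dist, _ = brute_shortest(weights, nodes)
    n = len(nodes)
    out = {}
    for v in range(n):
        s = sum(1.0 / dist[u, v] for u in range(n) if u != v and np.isfinite(dist[u, v]) and dist[u, v] > 0)
        out[nodes[v]] = s / (n - 1)
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_betweenness_and_closeness_match_bruteforce(self, seed):
        weights, nodes = random_digraph(seed)
        if not weights:
            pytest.skip("empty graph drawn")
        snap = snapshot_from_directed(weights, nodes)
        bc = compute_centrality(snap, "betweenness")
        oracle_bc = brute_betweenness(weights, nodes)
        for nd in nodes:
            assert bc[nd] == pytest.approx(oracle_bc[nd], abs=1e-9)
        inc = compute_centrality(snap, "incloseness")
        oracle_in = brute_harmonic_in(weights, nodes)
        for nd in nodes:
            assert inc[nd] == pytest.approx(oracle_in[nd], abs=1e-9)
        # outcloseness = incloseness on the reversed graph
        rev = {(v, u): w for (u, v), w in weights.items()}
        oracle_out = brute_harmonic_in(rev, nodes)
        outc = compute_centrality(snap, "outcloseness")
        for nd in nodes:
            assert outc[nd] == pytest.approx(oracle_out[nd], abs=1e-9)


class TestBasics:
    def test_star_degree(self):
        weights = {("h", leaf): 1.0 for leaf in ("a", "b", "c")}
        snap = snapshot_from_directed(weights, ["h", "a", "b", "c"])
        deg = compute_centrality(snap, "degree")
        assert deg["h"] == pytest.approx(3.0)
        assert all(deg[leaf] == pytest.approx(1.0) for leaf in "abc")
        assert compute_centrality(snap, "outdegree")["h"] == pytest.approx(3.0)
        assert compute_centrality(snap, "indegree")["a"] == pytest.approx(1.0)

    def test_directed_cycle_pagerank_uniform(self):
        weights = {("a", "b"): 1.0, ("b", "c"): 1.0, ("c", "a"): 1.0}
        snap = snapshot_from_directed(weights, ["a", "b", "c"])
        pr = compute_centrality(snap, "pagerank")
        assert np.allclose(pr.values, 1 / 3, atol=1e-9)
        assert pr.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unknown_measure_lists_valid(self):
        snap = snapshot_from_directed({("a", "b"): 1.0}, ["a", "b"])
        with pytest.raises(ValueError, match="degree"):
            compute_centrality(snap, "fame")

    def test_scale_invariance_of_rankings(self):
        weights, nodes = random_digraph(7)
        snap1 = snapshot_from_directed(weights, nodes)
        snap2 = snapshot_from_directed({e: 3.7 * w for e, w in weights.items()}, nodes)
        for measure in ("pagerank", "eigenvector", "hubs", "betweenness"):
            v1 = compute_centrality(snap1, measure)
            v2 = compute_centrality(snap2, measure)
            # these measures are invariant under uniform weight scaling, so
            # the values (hence any ranking) must coincide
            assert np.allclose(v1.values, v2.values, atol=1e-8)

    def test_disconnected_graph_not_fatal(self):
        snap = snapshot_from_directed({("a", "b"): 1.0}, ["a", "b", "c", "d"])
        for measure in ALL_MEASURES:
            vals = compute_centrality(snap, measure)
            assert np.all(np.isfinite(vals.values))
            assert np.all(vals.values >= 0)

    def test_symmetric_digraph_degree_identity(self):
        """On a snapshot whose edges are undirected ties, degree equals
        indegree + outdegree computed on the reciprocal directed view."""
        edges = {("a", "b"): Edge(0.5, 0.0, 1), ("b", "c"): Edge(0.25, 0.0, 1)}
        snap = NetworkSnapshot(nodes=["a", "b", "c"], edges=edges, t_window=None, f_window=None)
        deg = compute_centrality(snap, "degree")
        din = compute_centrality(snap, "indegree")
        dout = compute_centrality(snap, "outdegree")
        assert np.allclose(2 * deg.values, (din + dout).values)


class TestDynamicCentrality:
    @staticmethod
    def make_dyn(per_window_edges, nodes):
        snaps = [
            NetworkSnapshot(nodes=nodes, edges=e, t_window=(i, i + 1.0), f_window=None)
            for i, e in enumerate(per_window_edges)
        ]
        return DynamicNetwork(snapshots=snaps, w=1.0, t_min=0.0, t_max=float(len(snaps)))

    def test_time_invariant_network_constant_series(self):
        edges = {("a", "b"): Edge(0.5, -1.0, 1)}
        dyn = self.make_dyn([dict(edges)] * 4, ["a", "b"])
        dc = dynamic_centrality(dyn, "degree")
        assert np.allclose(dc.series.values, dc.series.values[:, :1])

    def test_edge_appearing_in_window_three(self):
        base = {("a", "b"): Edge(0.5, -1.0, 1)}
        with_h = dict(base)
        with_h[("a", "h")] = Edge(0.9, -1.0, 1)
        dyn = self.make_dyn([base, base, with_h, with_h], ["a", "b", "h"])
        dc = dynamic_centrality(dyn, "degree")
        assert np.allclose(dc.series.loc["h"].values, [0, 0, 0.9, 0.9])

    def test_mean_series_definition(self):
        edges = {("a", "b"): Edge(0.5, -1.0, 1), ("b", "c"): Edge(0.3, -1.0, 1)}
        dyn = self.make_dyn([edges, {}], ["a", "b", "c"])
        dc = dynamic_centrality(dyn, "pagerank")
        assert np.allclose(dc.mean_series.values, dc.series.values.mean(axis=0))


class TestCharacteristicCentrality:
    @staticmethod
    def weighted_snapshot(seed=0, n=8):
        rng = np.random.default_rng(seed)
        nodes = [f"n{i}" for i in range(n)]
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.6:
                    edges[(nodes[i], nodes[j])] = Edge(
                        float(rng.uniform(0.1, 1.0)), float(rng.choice([-1.0, 1.0])), 1
                    )
        return NetworkSnapshot(nodes=nodes, edges=edges, t_window=None, f_window=None)

    def test_contributions_sum_to_100(self):
        cc = characteristic_centrality(self.weighted_snapshot())
        sums = cc.contributions.sum(axis=0)
        assert np.allclose(sums.values, 100.0, atol=1e-9)
        assert np.all(np.diff(cc.variance_fraction) <= 1e-12)

    def test_collinear_measures_share_pc1(self):
        """degree and eigenvector engineered collinear; betweenness varies
        independently and should dominate a later component."""
        snap = self.weighted_snapshot(3)
        import microcoh.centrality as cen

        table = cen.centrality_table(snap).values
        base = table["degree"].to_numpy()
        rng = np.random.default_rng(1)
        indep = rng.permutation(base) + rng.normal(0, 0.3, base.size)
        fake = table.copy()
        fake["eigenvector"] = 2.0 * base + 1.0
        fake["betweenness"] = indep

        X = fake[["degree", "eigenvector", "betweenness"]].to_numpy(dtype=float)
        X = (X - X.mean(0)) / X.std(0)
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        contrib = 100 * vt.T**2 / (vt.T**2).sum(axis=0, keepdims=True)
        # degree & eigenvector near-equal on PC1; betweenness on a later PC
        assert contrib[0, 0] == pytest.approx(contrib[1, 0], abs=1.0)
        assert contrib[2, 1:].max() > contrib[2, 0]

    def test_too_few_nodes_rejected(self):
        snap = NetworkSnapshot(
            nodes=["a", "b"], edges={("a", "b"): Edge(0.5, 0.0, 1)}, t_window=None, f_window=None
        )
        with pytest.raises(ValueError, match="3 nodes"):
            characteristic_centrality(snap)
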