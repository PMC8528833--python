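"""Weighted centrality measures, dynamic centrality, and PCA-based measure ranking.

Ten measures are exposed: for the undirected view of a snapshot — weighted
degree (strength), harmonic closeness and eigenvector centrality; for the
directed view — weighted in/out-degree, in/out harmonic closeness,
betweenness, HITS hubs and PageRank. Path-based measures travel along
``distance = 1/weight`` (strong edges are short). "Characteristic
centrality" ranks the measures themselves by their contribution to the
principal components of the node x measure matrix, a data-driven way to pick
the measure that best summarises a given network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network_dynamics import DynamicNetwork, NetworkSnapshot

__all__ = [
    "UNDIRECTED_MEASURES",
    "DIRECTED_MEASURES",
    "ALL_MEASURES",
    "CentralityTable",
    "DynamicCentrality",
    "compute_centrality",
    "centrality_table",
    "dynamic_centrality",
    "characteristic_centrality",
]

UNDIRECTED_MEASURES = ("degree", "closeness", "eigenvector")
DIRECTED_MEASURES = (
    "indegree",
    "outdegree",
    "incloseness",
    "outcloseness",
    "betweenness",
    "hubs",
    "pagerank",
)
ALL_MEASURES = UNDIRECTED_MEASURES + DIRECTED_MEASURES


@dataclass
class CentralityTable:
    """Node x measure matrix for one snapshot."""

    values: pd.DataFrame  # index: nodes, columns: measures

    def to_csv(self, path) -> None:
        long = self.values.reset_index(names="node").melt(
            id_vars="node", var_name="measure", value_name="value"
        )
        long.to_csv(path, index=False)


@dataclass
class DynamicCentrality:
    """One measure tracked across the snapshots of a dynamic network."""

    series: pd.DataFrame  # index: nodes, columns: window index (1-based)
    measure: str
    w: float

    @property
    def mean_series(self) -> pd.Series:
        """Per-window mean over nodes."""
        return self.series.mean(axis=0)


def _add_distance(g) -> None:
    for u, v, d in g.edges(data=True):
        d["distance"] = 1.0 / d["weight"] if d["weight"] > 0 else np.inf


def _harmonic(g, n_nodes: int) -> dict:
    """Harmonic closeness on 1/weight distances, normalised by n-1.

    Defined (as 0) for isolated nodes and disconnected graphs, which real
    significant-edge networks frequently are.
    """
    raw = nx.harmonic_centrality(g, distance="distance")
    denom = max(n_nodes - 1, 1)
    return {n: v / denom for n, v in raw.items()}


def _unit_max(scores: dict) -> dict:
    m = max(abs(v) for v in scores.values()) if scores else 0.0
    if m <= 0:
        return {n: 0.0 for n in scores}
    return {n: abs(v) / m for n, v in scores.items()}


def compute_centrality(
    snapshot: NetworkSnapshot, measure: str, tie_tol: float = 0.1
) -> pd.Series:
    """One centrality measure for every node of a snapshot.

    Strength-style measures sum incident edge weights; closeness and
    betweenness use Dijkstra distances on 1/weight; eigenvector and hubs are
    normalised to unit maximum; pagerank (damping 0.85) sums to 1.
    """
    if measure not in ALL_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; valid: {list(ALL_MEASURES)}")
    nodes = snapshot.nodes
    if measure in UNDIRECTED_MEASURES:
        g = snapshot.to_undirected_graph()
    else:
        g = snapshot.to_directed_graph(tie_tol=tie_tol)
    _add_distance(g)

    if measure == "degree":
        scores = dict(g.degree(weight="weight"))
    elif measure == "indegree":
        scores = dict(g.in_degree(weight="weight"))
    elif measure == "outdegree":
        scores = dict(g.out_degree(weight="weight"))
    elif measure == "closeness":
        scores = _harmonic(g, len(nodes))
    elif measure == "incloseness":
        # harmonic_centrality sums over paths u -> v into v (incoming reach)
        scores = _harmonic(g, len(nodes))
    elif measure == "outcloseness":
        scores = _harmonic(g.reverse(copy=True), len(nodes))
    elif measure == "betweenness":
        scores = nx.betweenness_centrality(g, weight="distance", normalized=True)
    elif measure == "eigenvector":
        scores = _eigenvector_safe(g)
    elif measure == "hubs":
        scores = _hits_safe(g)
    elif measure == "pagerank":
        if g.number_of_edges() == 0:
            scores = {n: 1.0 / len(nodes) for n in nodes}
        else:
            scores = nx.pagerank(g, alpha=0.85, weight="weight", tol=1e-12, max_iter=500)
    return pd.Series({n: float(scores.get(n, 0.0)) for n in nodes}, name=measure).loc[nodes]


def _eigenvector_safe(g: nx.Graph) -> dict:
    if g.number_of_edges() == 0:
        return {n: 0.0 for n in g.nodes}
    try:
        scores = nx.eigenvector_centrality_numpy(g, weight="weight")
    except Exception:
        scores = nx.eigenvector_centrality(g, weight="weight", max_iter=2000, tol=1e-10)
    return _unit_max(scores)


def _hits_safe(g: nx.DiGraph) -> dict:
    if g.number_of_edges() == 0:
        return {n: 0.0 for n in g.nodes}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # uniform start vector: the underlying sparse SVD defaults to a
        # random one, which would make results run-to-run nondeterministic
        hubs, _ = nx.hits(g, max_iter=1000, tol=1e-12, nstart={n: 1.0 for n in g})
    return _unit_max(hubs)


def centrality_table(snapshot: NetworkSnapshot, measures=ALL_MEASURES) -> CentralityTable:
    cols = {m: compute_centrality(snapshot, m) for m in measures}
    return CentralityTable(values=pd.DataFrame(cols, index=snapshot.nodes))


def dynamic_centrality(dyn: DynamicNetwork, measure: str) -> DynamicCentrality:
    """Track one measure across all snapshots; windows without edges yield zeros."""
    cols = {}
    for t, snap in enumerate(dyn.snapshots, start=1):
        cols[t] = compute_centrality(snap, measure)
    series = pd.DataFrame(cols, index=dyn.nodes)
    return DynamicCentrality(series=series, measure=measure, w=dyn.w)


@dataclass
class CharacteristicCentrality:
    """PCA over the node x measure matrix: which measures carry the variance."""

    contributions: pd.DataFrame  # measures x PCs, percent, each column sums to 100
    variance_fraction: np.ndarray  # per retained PC
    ranked_measures: list[str]  # by contribution to PC1, descending
    dropped: list[str]  # constant measure columns removed before PCA


def characteristic_centrality(
    snapshot: NetworkSnapshot, measures=ALL_MEASURES, n_components: int = 3
) -> CharacteristicCentrality:
    """Rank centrality measures by their contribution to the leading PCs.

    The node x measure matrix is z-scored per measure (measures live on
    incommensurable scales), decomposed by SVD, and the contribution of
    measure m to PC k is 100 * loading(m,k)^2 / sum_m loading(m,k)^2.
    Constant measure columns are dropped with a warning; needs >= 3 nodes.
    """
    if len(snapshot.nodes) < 3:
        raise ValueError("characteristic centrality requires at least 3 nodes")
    table = centrality_table(snapshot, measures).values
    keep, dropped = [], []
    for m in table.columns:
        (dropped if np.isclose(table[m].std(ddof=0), 0.0) else keep).append(m)
    if dropped:
        warnings.warn(f"dropping constant measure column(s): {dropped}", stacklevel=2)
    if len(keep) < 2:
        raise ValueError("need at least 2 non-constant measures")
    X = table[keep].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(s))
    var_frac = (s**2 / (s**2).sum())[:k]
    loadings = vt[:k].T  # measures x PCs
    contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0, keepdims=True)
    contributions = pd.DataFrame(contrib, index=keep, columns=[f"PC{i+1}" for i in range(k)])
    ranked = list(contributions.sort_values("PC1", ascending=False).index)
    return CharacteristicCentrality(
        contributions=contributions,
        variance_fraction=var_frac,
        ranked_measures=ranked,
        dropped=dropped,
    )
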