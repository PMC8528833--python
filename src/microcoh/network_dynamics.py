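"""Time–frequency targeted network snapshots, dynamic networks and global connectivity.

A *snapshot* collapses the per-pair coherency maps inside a user-chosen
time–frequency window into a weighted graph over channels: the edge weight is
the mean |IWTC| over qualifying bins (optionally restricted to significant
bins), and a signed direction score (mean sign of the imaginary part)
orients the edge. A *dynamic network* is a sequence of snapshots over fixed
time steps of width ``w``; Global Microscale Connectivity (GMC) is the mean
edge weight over all channel pairs, with absent edges counted as zero so the
measure is comparable across subjects of different network sparsity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .coherency import CoherencyMap
from .significance import SignificanceMask

__all__ = [
    "Edge",
    "NetworkSnapshot",
    "DynamicNetwork",
    "build_snapshot",
    "build_dynamic_network",
    "global_microscale_connectivity",
    "force_layout",
    "layered_layout",
    "LayeredLayout",
]

_TOL = 1e-9


@dataclass
class Edge:
    weight: float  # mean |iwtc| over qualifying bins, in [0, 1]
    direction: float  # mean sign(iwtc), in [-1, 1]; >0 means second label leads first
    n_bins: int


@dataclass
class NetworkSnapshot:
    """Weighted graph over channels aggregated in one time–frequency window."""

    nodes: list[str]
    edges: dict[tuple[str, str], Edge]
    t_window: tuple[float, float] | None  # None = full
    f_window: tuple[float, float] | None
    significant_only: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (u, v), e in self.edges.items():
            if u == v:
                raise ValueError("self-edges are not allowed")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError(f"edge ({u},{v}) references unknown node")
            if e.weight < 0:
                raise ValueError("edge weights must be non-negative")

    def to_undirected_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), e in self.edges.items():
            g.add_edge(u, v, weight=e.weight, direction=e.direction)
        return g

    def to_directed_graph(self, tie_tol: float = 0.1) -> nx.DiGraph:
        """Orient edges by the direction score (positive: second label leads,
        i.e. flow v -> u). Near-zero scores (|score| <= tie_tol) are treated as
        reciprocal and added in both directions."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), e in self.edges.items():
            if e.direction > tie_tol:
                g.add_edge(v, u, weight=e.weight)
            elif e.direction < -tie_tol:
                g.add_edge(u, v, weight=e.weight)
            else:
                g.add_edge(u, v, weight=e.weight)
                g.add_edge(v, u, weight=e.weight)
        return g

    def export_edgelist(self, path: str | Path) -> None:
        """Write edges as CSV: src,dst,weight,direction (src -> dst is the flow)."""
        lines = ["src,dst,weight,direction"]
        for (u, v), e in sorted(self.edges.items()):
            src, dst = (v, u) if e.direction > 0 else (u, v)
            lines.append(f"{src},{dst},{e.weight:.6g},{e.direction:.6g}")
        Path(path).write_text("\n".join(lines) + "\n")

    def export_json(self, path: str | Path) -> None:
        payload = {
            "nodes": self.nodes,
            "t_window": self.t_window,
            "f_window": self.f_window,
            "significant_only": self.significant_only,
            "edges": [
                {"u": u, "v": v, "weight": e.weight, "direction": e.direction, "n_bins": e.n_bins}
                for (u, v), e in sorted(self.edges.items())
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class DynamicNetwork:
    """A sequence of snapshots covering [t_min, t_max] in steps of width w seconds."""

    snapshots: list[NetworkSnapshot]
    w: float
    t_min: float
    t_max: float

    @property
    def n_windows(self) -> int:
        return len(self.snapshots)

    @property
    def nodes(self) -> list[str]:
        return self.snapshots[0].nodes


def _window_bins(
    cmap: CoherencyMap,
    t_window: tuple[float, float] | None,
    f_window: tuple[float, float] | None,
) -> np.ndarray:
    """Boolean (n_scales, n_times) selector for a closed time x frequency window."""
    t_sel = np.ones(cmap.times.size, dtype=bool)
    if t_window is not None:
        t0, t1 = t_window
        t_sel = (cmap.times >= t0 - _TOL) & (cmap.times <= t1 + _TOL)
    f_sel = np.ones(cmap.freqs.size, dtype=bool)
    if f_window is not None:
        f0, f1 = f_window
        f_sel = (cmap.freqs >= f0 - _TOL) & (cmap.freqs <= f1 + _TOL)
    return f_sel[:, None] & t_sel[None, :]


def _parse_window(win) -> tuple[float, float] | None:
    if win is None or (isinstance(win, str) and win.lower() == "full"):
        return None
    t0, t1 = float(win[0]), float(win[1])
    if t1 < t0:
        raise ValueError(f"window bounds reversed: {win}")
    return (t0, t1)


def build_snapshot(
    maps: dict[tuple[str, str], CoherencyMap],
    mask: dict[tuple[str, str], SignificanceMask] | None = None,
    t_window=None,
    f_window=None,
) -> NetworkSnapshot:
    """Aggregate coherency maps into a static network over a time–frequency window.

    Per pair, the edge weight is the mean |IWTC| over window bins inside the
    COI (further restricted to significant bins when ``mask`` is given); the
    direction score is the mean sign of the IWTC over the same bins. Pairs
    with no qualifying bin get no edge. ``t_window``/``f_window`` accept
    ``(lo, hi)``, ``None`` or ``"full"``.
    """
    if not maps:
        raise ValueError("maps is empty")
    t_win, f_win = _parse_window(t_window), _parse_window(f_window)
    nodes = sorted({lbl for pair in maps for lbl in pair})
    edges: dict[tuple[str, str], Edge] = {}
    any_bins = False
    for pair, cmap in maps.items():
        sel = _window_bins(cmap, t_win, f_win)
        if sel.any():
            any_bins = True
        sel &= cmap.coi & cmap.valid
        if mask is not None:
            sel &= mask[pair].flags
        n = int(sel.sum())
        if n == 0:
            continue
        iw = cmap.rhat.imag[sel]
        edges[pair] = Edge(weight=float(np.abs(iw).mean()), direction=float(np.sign(iw).mean()), n_bins=n)
    if not any_bins:
        raise ValueError("time–frequency window does not intersect the map axes")
    return NetworkSnapshot(
        nodes=nodes,
        edges=edges,
        t_window=t_win,
        f_window=f_win,
        significant_only=mask is not None,
    )


def build_dynamic_network(
    maps: dict[tuple[str, str], CoherencyMap],
    mask: dict[tuple[str, str], SignificanceMask] | None = None,
    w: float = 0.1,
    f_window=None,
) -> DynamicNetwork:
    """Split the maps' time span [t_min, t_max] into ceil(T/w) snapshots of width w.

    Snapshot t covers ``(t_min + (t-1)w, t_min + t*w]``; the first window also
    takes the t_min bin, and the last window may be shorter than w.
    """
    if w <= 0:
        raise ValueError("w must be positive")
    some_map = next(iter(maps.values()))
    t_min, t_max = float(some_map.times[0]), float(some_map.times[-1])
    T = t_max - t_min
    if w > T + _TOL:
        raise ValueError(f"w={w} exceeds the record span T={T}")
    n = int(np.ceil((T - _TOL) / w))
    snapshots = []
    for t in range(1, n + 1):
        lo = t_min + (t - 1) * w
        hi = t_min + t * w if t < n else t_max
        snap = build_snapshot(maps, mask, t_window=(lo, hi), f_window=f_window)
        if t > 1:
            # drop the boundary bin shared with the previous closed window
            snap = _shift_open_left(maps, mask, (lo, hi), f_window, snap)
        snap.meta["window_index"] = t
        snap.meta["short_window"] = bool(t == n and (T % w) > _TOL)
        snapshots.append(snap)
    return DynamicNetwork(snapshots=snapshots, w=float(w), t_min=t_min, t_max=t_max)


def _shift_open_left(maps, mask, t_win, f_window, snap: NetworkSnapshot) -> NetworkSnapshot:
    """Rebuild a snapshot with a left-open time window (t0, t1] so windows partition bins."""
    some_map = next(iter(maps.values()))
    times = some_map.times
    after = times[times > t_win[0] + _TOL]
    if after.size == 0:
        return snap
    lo = float(after[0])
    try:
        out = build_snapshot(maps, mask, t_window=(lo, t_win[1]), f_window=f_window)
    except ValueError:
        out = NetworkSnapshot(nodes=snap.nodes, edges={}, t_window=t_win, f_window=snap.f_window,
                              significant_only=snap.significant_only)
    out.t_window = t_win
    return out


def global_microscale_connectivity(snapshot: NetworkSnapshot, over: str = "all") -> float:
    """GMC: mean edge weight over node pairs.

    ``over="all"`` (default) averages over all C(n,2) pairs with absent edges
    as 0, making GMC sensitive to network density and comparable across
    subjects; ``over="existing"`` averages only over present edges.
    """
    n = len(snapshot.nodes)
    if n < 2:
        raise ValueError("GMC requires at least 2 nodes")
    total = sum(e.weight for e in snapshot.edges.values())
    if over == "existing":
        return total / len(snapshot.edges) if snapshot.edges else 0.0
    if over != "all":
        raise ValueError("over must be 'all' or 'existing'")
    return total / (n * (n - 1) / 2)


def force_layout(snapshot: NetworkSnapshot, seed: int = 0, iterations: int = 200) -> dict[str, tuple[float, float]]:
    """Force-directed (Fruchterman–Reingold) node coordinates, unit-box normalised.

    Attraction is proportional to edge weight; deterministic under ``seed``.
    A single node is placed at the origin.
    """
    if not snapshot.nodes:
        raise ValueError("snapshot has no nodes")
    if len(snapshot.nodes) == 1:
        return {snapshot.nodes[0]: (0.0, 0.0)}
    g = snapshot.to_undirected_graph()
    pos = nx.spring_layout(g, seed=seed, iterations=iterations, weight="weight")
    xy = np.array([pos[n] for n in snapshot.nodes])
    span = xy.max(axis=0) - xy.min(axis=0)
    span[span < _TOL] = 1.0
    xy = (xy - xy.min(axis=0)) / span
    return {n: (float(x), float(y)) for n, (x, y) in zip(snapshot.nodes, xy)}


@dataclass
class LayeredLayout:
    """Hierarchical (Sugiyama-style) layering of a directed snapshot."""

    layer: dict[str, int]
    order: dict[str, int]  # position within the layer after barycenter sweeps
    feedback_edges: list[tuple[str, str]]  # removed to break cycles


def layered_layout(snapshot: NetworkSnapshot, tie_tol: float = 0.1) -> LayeredLayout:
    """Layer nodes so retained directed edges point to strictly deeper layers.

    Heuristic pipeline: greedy cycle breaking (repeatedly remove the
    minimum-weight edge of a remaining cycle, reporting it as feedback),
    longest-path layering from the sources, then a few barycenter ordering
    sweeps within layers. Edges with |direction score| <= tie_tol are treated
    as undirected and excluded from layering. Never fails on cyclic input.
    """
    g = snapshot.to_directed_graph(tie_tol=tie_tol)
    # reciprocal (tied) pairs are excluded from the hierarchy
    for u, v in list(g.edges):
        if g.has_edge(v, u) and g.has_edge(u, v):
            g.remove_edge(u, v)
            g.remove_edge(v, u)
    feedback: list[tuple[str, str]] = []
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        u, v, *_ = min(cycle, key=lambda e: g.edges[e[0], e[1]]["weight"])
        g.remove_edge(u, v)
        feedback.append((u, v))

    layer = {n: 0 for n in g.nodes}
    for n in nx.topological_sort(g):
        preds = list(g.predecessors(n))
        if preds:
            layer[n] = max(layer[p] for p in preds) + 1

    # barycenter ordering within layers
    by_layer: dict[int, list[str]] = {}
    for n, l in layer.items():
        by_layer.setdefault(l, []).append(n)
    order = {n: i for l in sorted(by_layer) for i, n in enumerate(sorted(by_layer[l]))}
    for _ in range(3):
        for l in sorted(by_layer)[1:]:
            def bary(n: str) -> float:
                preds = [p for p in g.predecessors(n)]
                return float(np.mean([order[p] for p in preds])) if preds else order[n]
            ranked = sorted(by_layer[l], key=lambda n: (bary(n), n))
            for i, n in enumerate(ranked):
                order[n] = i
    return LayeredLayout(layer=layer, order=order, feedback_edges=feedback)
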