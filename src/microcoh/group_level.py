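"""Multi-subject aggregation: grand averages, PCA network modules, group effect size.

Subjects enter as network snapshots over a common channel montage. The stack
``G`` (subjects x connection pairs) supports the grand average (columnwise
mean), PCA module detection after subject-specific mean normalisation
(row-centering), and a two-group comparison of Global Microscale
Connectivity summarised by Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .network_dynamics import NetworkSnapshot

__all__ = [
    "GroupStack",
    "PCAModules",
    "EffectSize",
    "grand_average",
    "network_modules_pca",
    "group_effect_size",
]


@dataclass
class GroupStack:
    """Subjects x connection-pairs matrix of edge weights (absent edges are 0)."""

    G: np.ndarray  # (n_subjects, n_pairs)
    subject_ids: list[str]
    pair_labels: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("G must be 2-D (subjects x pairs)")
        if self.G.shape != (len(self.subject_ids), len(self.pair_labels)):
            raise ValueError("G shape must match subject_ids x pair_labels")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G contains missing values")

    @classmethod
    def from_snapshots(cls, snapshots: list[NetworkSnapshot], subject_ids: list[str] | None = None) -> "GroupStack":
        """Align subject snapshots on a common channel set; absent edges become 0.

        Raises ``ValueError`` naming the first subject whose channel set
        differs from the rest.
        """
        if not snapshots:
            raise ValueError("need at least one snapshot")
        if subject_ids is None:
            subject_ids = [f"s{i+1}" for i in range(len(snapshots))]
        nodes = snapshots[0].nodes
        for sid, snap in zip(subject_ids, snapshots):
            if snap.nodes != nodes:
                raise ValueError(
                    f"subject {sid!r} has channel set {snap.nodes}, expected {nodes}"
                )
        pairs = list(combinations(nodes, 2))
        G = np.zeros((len(snapshots), len(pairs)))
        for r, snap in enumerate(snapshots):
            for c, pair in enumerate(pairs):
                e = snap.edges.get(pair) or snap.edges.get(pair[::-1])
                if e is not None:
                    G[r, c] = e.weight
        return cls(G=G, subject_ids=list(subject_ids), pair_labels=pairs)

    @property
    def n_subjects(self) -> int:
        return self.G.shape[0]


def grand_average(stack: GroupStack) -> pd.Series:
    """Mean connectivity per pair across subjects."""
    if stack.n_subjects < 1:
        raise ValueError("empty stack")
    return pd.Series(stack.G.mean(axis=0), index=_pair_index(stack.pair_labels))


def _pair_index(pairs) -> pd.Index:
    return pd.Index(pairs, tupleize_cols=False, name="pair")


@dataclass
class PCAModules:
    """Leading network modules of the subject-centred connectivity stack."""

    components: np.ndarray  # (k, n_pairs) unit-norm loading vectors
    variance_fraction: np.ndarray  # (k,), non-increasing, sums to <= 1
    scores: np.ndarray  # (n_subjects, k)
    pair_labels: list[tuple[str, str]]

    def module_map(self, k: int = 0) -> pd.Series:
        """Loadings of component k projected back onto the connection pairs."""
        return pd.Series(self.components[k], index=_pair_index(self.pair_labels))


def network_modules_pca(stack: GroupStack, n_components: int = 3) -> PCAModules:
    """PCA of the subject x pair stack after subject-specific mean normalisation.

    Each subject's own mean connectivity is subtracted (row-centering, no
    variance scaling), then an SVD retains ``min(n_components, n_subjects-1)``
    components. Loading signs are fixed so each component's
    largest-magnitude entry is positive, making module maps reproducible
    under subject reordering.
    """
    if stack.n_subjects < 2:
        raise ValueError("PCA needs at least 2 subjects")
    X = stack.G - stack.G.mean(axis=1, keepdims=True)
    X = X - X.mean(axis=0, keepdims=True)
    total = (X**2).sum()
    if total <= 1e-30:
        raise ValueError("identical subjects: zero variance after centering")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, stack.n_subjects - 1)
    comps, sv, scores = vt[:k], s[:k], u[:, :k] * s[:k]
    for r in range(k):
        if comps[r, np.argmax(np.abs(comps[r]))] < 0:
            comps[r] = -comps[r]
            scores[:, r] = -scores[:, r]
    return PCAModules(
        components=comps,
        variance_fraction=sv**2 / (s**2).sum(),
        scores=scores,
        pair_labels=stack.pair_labels,
    )


@dataclass
class EffectSize:
    d: float  # group A minus group B, in pooled-SD units
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def group_effect_size(gmc_a, gmc_b, hedges: bool = False) -> EffectSize:
    """Cohen's d between two groups of per-subject GMC values.

    ``d = (mean_a - mean_b) / s_pooled`` with the n-1 pooled standard
    deviation; ``hedges`` applies the small-sample bias correction
    (Hedges' g). Sign convention: positive d means group A is larger.
    """
    a, b = np.asarray(gmc_a, dtype=float), np.asarray(gmc_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    if pooled <= 0:
        raise ValueError("zero pooled standard deviation")
    d = (a.mean() - b.mean()) / pooled
    if hedges:
        d *= 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return EffectSize(
        d=float(d),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(np.sqrt(va)),
        sd_b=float(np.sqrt(vb)),
        n_a=int(na),
        n_b=int(nb),
    )
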