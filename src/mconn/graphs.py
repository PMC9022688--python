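"""Binary graph metrics after proportional thresholding.

Compared networks are binarized at a matched edge density (a proportional
threshold) before metric computation, because density itself drives most
graph-theory parameters. Metrics follow the standard binary definitions:
global efficiency (mean inverse shortest-path length), local efficiency
(global efficiency of each node's neighbor-induced subgraph), transitivity
(closed triples over connected triples), and degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "BinaryGraph",
    "proportional_threshold",
    "global_efficiency",
    "local_efficiency",
    "local_efficiency_all",
    "transitivity",
    "degree",
]


@dataclass
class BinaryGraph:
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = A.astype(np.int8)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def density(self) -> float:
        n = self.n
        if n < 2:
            return 0.0
        return float(self.adjacency.sum()) / (n * (n - 1))


def proportional_threshold(W: np.ndarray, target_density: float) -> BinaryGraph:
    """Keep the top ``floor(d * n(n-1)/2)`` unique edges by weight; binarize.

    Ties are broken deterministically by lexicographic (i, j) order.
    Entries of -inf mark absent edges and are never kept.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.array_equal(np.nan_to_num(W, neginf=-1e300),
                          np.nan_to_num(W.T, neginf=-1e300)):
        raise ValueError("weight matrix must be symmetric")
    if not 0.0 <= target_density <= 1.0:
        raise ValueError("target_density must lie in [0, 1]")
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    eligible = np.flatnonzero(w > -np.inf)
    m_keep = min(int(np.floor(target_density * n * (n - 1) / 2)), eligible.size)
    A = np.zeros((n, n), dtype=np.int8)
    if m_keep > 0:
        # sort by weight descending, ties by (i, j) ascending
        order = np.lexsort((ju[eligible], iu[eligible], -w[eligible]))
        keep = eligible[order[:m_keep]]
        A[iu[keep], ju[keep]] = 1
        A[ju[keep], iu[keep]] = 1
    return BinaryGraph(adjacency=A)


def _pairwise_distances(A: np.ndarray) -> np.ndarray:
    return shortest_path(A.astype(float), method="D", unweighted=True, directed=False)


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over ordered node pairs (1/inf = 0)."""
    n = g.n
    if n < 2:
        raise ValueError("global efficiency requires n >= 2")
    d = _pairwise_distances(g.adjacency)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(g: BinaryGraph, node: int) -> float:
    """Global efficiency of the subgraph induced by ``node``'s neighbors.

    Nodes of degree < 2 have local efficiency 0.
    """
    A = g.adjacency
    nb = np.flatnonzero(A[node])
    if nb.size < 2:
        return 0.0
    sub = A[np.ix_(nb, nb)]
    return global_efficiency(BinaryGraph(adjacency=sub))


def local_efficiency_all(g: BinaryGraph) -> np.ndarray:
    return np.array([local_efficiency(g, i) for i in range(g.n)])


def transitivity(g: BinaryGraph) -> float:
    """T = 3 * triangles / connected triples; 0/0 defined as 0."""
    if g.n < 3:
        raise ValueError("transitivity requires n >= 3")
    A = g.adjacency.astype(np.int64)
    triangles = np.trace(A @ A @ A) / 6
    k = A.sum(axis=1)
    triples = (k * (k - 1) / 2).sum()
    if triples == 0:
        return 0.0
    return float(3.0 * triangles / triples)


def degree(g: BinaryGraph) -> np.ndarray:
    """Number of edges at each node (adjacency row sums)."""
    return g.adjacency.sum(axis=1).astype(int)
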