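"""Native implementations of the three ranked centrality indices.

Degree counts incident edges (co-occurrence weights ignored); PageRank runs
power iteration on the undirected graph with weight-proportional transitions
and uniform teleportation; betweenness uses Brandes' dependency accumulation
over unweighted shortest paths (endpoints excluded, undirected pair counts
halved).  These are the package's own implementations — reference graph
libraries appear only as independent oracles in the test suite.
"""

from __future__ import annotations

import dataclasses
from collections import deque

import numpy as np
from scipy import sparse

from .graph_model import Network

__all__ = ["CentralityVector", "degree", "pagerank", "betweenness"]


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the tolerance within max_iter."""


@dataclasses.dataclass
class CentralityVector:
    """Node -> value mapping plus the provenance of the computation."""

    values: dict[str, float]
    measure: str
    params: dict

    def __getitem__(self, node: str) -> float:
        return self.values[node]

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values, name=self.measure)


def degree(net: Network) -> CentralityVector:
    """Number of incident edges per node (unweighted)."""
    return CentralityVector(
        values={n: float(net.degree(n)) for n in net.nodes()},
        measure="degree",
        params={"weighted": False},
    )


def _adjacency(net: Network, weighted: bool = True):
    nodes = sorted(net.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    rows, cols, data = [], [], []
    for u, v, w in net.edges():
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
        data += [w if weighted else 1.0] * 2
    n = len(nodes)
    return nodes, sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def pagerank(
    net: Network,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> CentralityVector:
    """Stationary random-walk importance with uniform teleportation.

    Each undirected edge is traversable both ways with probability
    proportional to its weight.  Nodes without edges (dangling) spread their
    mass uniformly.  Iteration stops when the L1 change drops below ``tol``;
    the result sums to 1.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie strictly between 0 and 1")
    nodes, A = _adjacency(net, weighted=True)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    strength = np.asarray(A.sum(axis=1)).ravel()
    dangling = strength == 0
    inv = np.zeros(n)
    inv[~dangling] = 1.0 / strength[~dangling]
    # column-stochastic transition: M[j, i] = w_ij / s_i
    M = A.multiply(inv[:, None]).T.tocsr()

    x = np.full(n, 1.0 / n)
    teleport = (1.0 - damping) / n
    for _ in range(max_iter):
        x_new = damping * (M @ x + x[dangling].sum() / n) + teleport
        delta = float(np.abs(x_new - x).sum())
        x = x_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"PageRank did not converge in {max_iter} iterations "
            f"(residual {delta:.3e})"
        )
    x = x / x.sum()
    return CentralityVector(
        values={nodes[i]: float(x[i]) for i in range(n)},
        measure="pagerank",
        params={"damping": damping, "tol": tol},
    )


def betweenness(
    net: Network, normalized: bool = False, weighted_paths: bool = False
) -> CentralityVector:
    """Brandes betweenness over shortest paths.

    Paths are unweighted by default (co-occurrence weights are counts, not
    distances); ``weighted_paths=True`` uses Dijkstra with distance = 1/w.
    Endpoints are excluded; each unordered pair is counted once (undirected
    halving).  ``normalized=True`` divides by ``(n-1)(n-2)/2``.
    """
    import heapq

    nodes = sorted(net.nodes())
    adj = {u: sorted(net.neighbors(u)) for u in nodes}
    bc = dict.fromkeys(nodes, 0.0)

    for s in nodes:
        stack: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        if not weighted_paths:
            dist = dict.fromkeys(nodes, -1)
            dist[s] = 0
            queue = deque([s])
            while queue:
                v = queue.popleft()
                stack.append(v)
                for w, _ in adj[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        queue.append(w)
                    if dist[w] == dist[v] + 1:
                        sigma[w] += sigma[v]
                        pred[w].append(v)
        else:
            # Dijkstra variant of Brandes (Eppstein-style heap entries);
            # sigma is globally rescaled per source, which cancels in the
            # delta ratios.
            sigma = dict.fromkeys(nodes, 0.0)
            sigma[s] = 1.0
            done: dict[str, float] = {}
            seen = {s: 0.0}
            tie = 0
            heap = [(0.0, tie, s, s)]
            while heap:
                d, _, p, v = heapq.heappop(heap)
                if v in done:
                    continue
                sigma[v] += sigma[p]
                stack.append(v)
                done[v] = d
                for w, wt in adj[v]:
                    nd = d + 1.0 / wt
                    if w not in done and (w not in seen or nd < seen[w]):
                        seen[w] = nd
                        tie += 1
                        heapq.heappush(heap, (nd, tie, v, w))
                        sigma[w] = 0.0
                        pred[w] = [v]
                    elif nd == seen.get(w):
                        sigma[w] += sigma[v]
                        pred[w].append(v)
        delta = dict.fromkeys(nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]

    n = len(nodes)
    scale = 0.5  # undirected: each pair visited from both endpoints
    if normalized:
        denom = (n - 1) * (n - 2) / 2.0
        scale = 0.0 if denom == 0 else scale / denom
    return CentralityVector(
        values={v: bc[v] * scale for v in nodes},
        measure="betweenness",
        params={"normalized": normalized, "weighted_paths": False},
    )
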