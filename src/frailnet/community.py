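"""Newman modularity and a two-phase greedy (Louvain-style) optimizer.

Modularity of a partition on a weighted undirected graph:

    Q = sum_c [ W_c / W  -  ( S_c / 2W )^2 ]

with ``W`` the total edge weight, ``W_c`` the intra-community weight and
``S_c`` the summed weighted degree (strength) of community ``c``.  The
optimizer alternates (1) single-node moves to the neighboring community
with the largest positive modularity gain, sweep order shuffled by the
seed, and (2) aggregation of communities into a weighted super-graph with
self-loops, until no move improves Q.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .graph_model import Network

__all__ = ["Partition", "modularity", "louvain"]

_GAIN_EPS = 1e-12


@dataclasses.dataclass
class Partition:
    """Node -> community assignment with contiguous integer labels."""

    membership: dict[str, int]

    def __post_init__(self) -> None:
        self.membership = dict(self.membership)
        self._relabel()

    def _relabel(self) -> None:
        seen: dict[int, int] = {}
        for node, c in self.membership.items():
            if c not in seen:
                seen[c] = len(seen)
            self.membership[node] = seen[c]

    def __getitem__(self, node: str) -> int:
        return self.membership[node]

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values())) if self.membership else 0

    def members(self, label: int) -> list[str]:
        return [n for n, c in self.membership.items() if c == label]

    def communities(self) -> list[list[str]]:
        out: list[list[str]] = [[] for _ in range(self.n_communities)]
        for n, c in self.membership.items():
            out[c].append(n)
        return out

    @classmethod
    def singletons(cls, nodes) -> "Partition":
        return cls({n: i for i, n in enumerate(nodes)})


def modularity(net: Network, partition: Partition) -> float:
    """Newman-Girvan modularity of ``partition`` on ``net``; Q in [-1, 1]."""
    membership = partition.membership
    missing = [n for n in net.nodes() if n not in membership]
    if missing:
        raise ValueError(f"partition misses {len(missing)} nodes "
                         f"(e.g. {missing[0]!r})")
    W = net.total_weight()
    if W <= 0:
        raise ValueError("modularity is undefined on an edgeless network")
    intra: dict[int, float] = {}
    strength: dict[int, float] = {}
    for u, v, w in net.edges():
        cu, cv = membership[u], membership[v]
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + w
    for n in net.nodes():
        c = membership[n]
        strength[c] = strength.get(c, 0.0) + net.strength(n)
    q = 0.0
    for c in set(membership.values()):
        q += intra.get(c, 0.0) / W - (strength.get(c, 0.0) / (2.0 * W)) ** 2
    return q


# ---------------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------------

class _Agg:
    """Aggregated weighted graph as index-based adjacency with self-loops."""

    def __init__(self, adj: list[dict[int, float]], self_loops: list[float]):
        self.adj = adj
        self.loops = self_loops
        # strength counts self-loops twice (both stubs)
        self.strength = [
            sum(nbrs.values()) + 2.0 * self_loops[i]
            for i, nbrs in enumerate(adj)
        ]

    @classmethod
    def from_network(cls, net: Network, order: list[str]):
        index = {n: i for i, n in enumerate(order)}
        adj: list[dict[int, float]] = [{} for _ in order]
        loops = [0.0] * len(order)
        for u, v, w in net.edges():
            iu, iv = index[u], index[v]
            adj[iu][iv] = adj[iu].get(iv, 0.0) + w
            adj[iv][iu] = adj[iv].get(iu, 0.0) + w
        return cls(adj, loops)

    @property
    def n(self) -> int:
        return len(self.adj)

    def total_weight(self) -> float:
        inter = sum(sum(nbrs.values()) for nbrs in self.adj) / 2.0
        return inter + sum(self.loops)


def _one_level(agg: _Agg, rng: np.random.Generator, resolution: float,
               init: list[int] | None = None):
    """Phase 1: greedy single-node moves.  Returns (labels, improved)."""
    n = agg.n
    labels = list(range(n)) if init is None else list(init)
    comm_strength: dict[int, float] = {}
    for i in range(n):
        comm_strength[labels[i]] = comm_strength.get(labels[i], 0.0) + agg.strength[i]
    two_w = 2.0 * agg.total_weight()
    improved = False
    moved = True
    while moved:
        moved = False
        order = np.arange(n)
        rng.shuffle(order)
        for i in order:
            i = int(i)
            ci = labels[i]
            k_i = agg.strength[i]
            # weights from i to each neighboring community
            links: dict[int, float] = {}
            for j, w in agg.adj[i].items():
                links[labels[j]] = links.get(labels[j], 0.0) + w
            comm_strength[ci] -= k_i
            base = links.get(ci, 0.0) - resolution * comm_strength[ci] * k_i / two_w
            best_c, best_gain = ci, 0.0
            for c in sorted(links):
                if c == ci:
                    continue
                gain = (links[c] - resolution * comm_strength.get(c, 0.0) * k_i / two_w) - base
                if gain > best_gain + _GAIN_EPS or (
                    gain > best_gain - _GAIN_EPS and gain > _GAIN_EPS and c < best_c
                ):
                    best_c, best_gain = c, gain
            comm_strength[best_c] = comm_strength.get(best_c, 0.0) + k_i
            if best_c != ci:
                labels[i] = best_c
                moved = True
                improved = True
    return labels, improved


def _aggregate(agg: _Agg, labels: list[int]) -> tuple[_Agg, list[int]]:
    remap: dict[int, int] = {}
    for c in labels:
        if c not in remap:
            remap[c] = len(remap)
    labels = [remap[c] for c in labels]
    k = len(remap)
    adj: list[dict[int, float]] = [{} for _ in range(k)]
    loops = [0.0] * k
    for i in range(agg.n):
        ci = labels[i]
        loops[ci] += agg.loops[i]
        for j, w in agg.adj[i].items():
            if j < i:
                continue
            cj = labels[j]
            if ci == cj:
                loops[ci] += w
            else:
                adj[ci][cj] = adj[ci].get(cj, 0.0) + w
                adj[cj][ci] = adj[cj].get(ci, 0.0) + w
    return _Agg(adj, loops), labels


def louvain(
    net: Network, seed: int, resolution: float = 1.0, n_restarts: int = 8
) -> tuple[Partition, float]:
    """Two-phase modularity maximization; deterministic for a fixed seed.

    Ties between equal-gain moves go to the lowest community label.  Being
    greedy, a single pass can stall in a local optimum, so the optimizer
    runs ``n_restarts`` independent seeded sweeps (each iterated until Q
    stops improving) and keeps the best-Q partition; all restart streams
    derive from ``seed``, so the result is reproducible.  The returned Q is
    re-evaluated with :func:`modularity` on the original graph (at
    resolution 1 this equals the optimizer's internal objective).
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if net.total_weight() <= 0:
        raise ValueError("louvain requires at least one weighted edge")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    order = sorted(net.nodes())
    base = _Agg.from_network(net, order)

    best: tuple[Partition, float] | None = None
    for child in np.random.SeedSequence(seed).spawn(n_restarts):
        rng = np.random.default_rng(child)
        node_comm = list(range(base.n))
        prev_q = None
        while True:
            node_comm = _cycle(base, node_comm, rng, resolution)
            partition = Partition(
                {order[i]: node_comm[i] for i in range(len(order))}
            )
            q = modularity(net, partition)
            if prev_q is not None and q <= prev_q + _GAIN_EPS:
                break
            prev_q = q
            node_comm = [partition[order[i]] for i in range(len(order))]
        if best is None or q > best[1] + _GAIN_EPS:
            best = (partition, q)
    return best


def _cycle(base: _Agg, init: list[int], rng, resolution: float) -> list[int]:
    """One full Louvain cycle (phase 1 + repeated aggregation) from ``init``."""
    labels, _ = _one_level(base, rng, resolution, init=init)
    agg, labels = _aggregate(base, labels)
    node_comm = list(labels)
    while True:
        labels, improved = _one_level(agg, rng, resolution)
        if not improved and agg.n == len(set(labels)):
            break
        agg, labels = _aggregate(agg, labels)
        node_comm = [labels[c] for c in node_comm]
        if not improved:
            break
    return node_comm
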