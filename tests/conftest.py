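"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, dense
linear algebra) and never share code with the package implementations they
check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

import frailnet as fn
from frailnet import vocab
from frailnet.graph_model import Network
from frailnet.record_linkage import FeatureTable

# ---------------------------------------------------------------------------
# fixture builders
# ---------------------------------------------------------------------------


def make_feature_table(rows: list[dict]) -> FeatureTable:
    """Build a FeatureTable from sparse row dicts (categories default False)."""
    full = []
    for i, row in enumerate(rows):
        base = {
            "patient_id": row.get("patient_id", f"P{i:03d}"),
            "age_class": row.get("age_class", "75-79"),
            "gender": row.get("gender", "Male"),
            "marital_status": row.get("marital_status", "Married"),
            "family_status": row.get("family_status", "NoCriticalFamily"),
            "frailty_status": row.get("frailty_status", "NF"),
        }
        cats = row.get("categories", ())
        base["hospitalized"] = row.get("hospitalized", bool(cats))
        for c in vocab.CLINICAL_CATEGORIES:
            base[c] = c in cats
        full.append(base)
    table = FeatureTable(pd.DataFrame(full))
    table.category_names = tuple(vocab.CLINICAL_CATEGORIES)
    return table


def make_graph(edges, weights=None, n_nodes=None) -> Network:
    """Small generic graph with string node ids '0', '1', ..."""
    nodes = {str(x) for e in edges for x in e}
    if n_nodes is not None:
        nodes |= {str(i) for i in range(n_nodes)}
    net = Network()
    for n in sorted(nodes, key=lambda s: (len(s), s)):
        net.add_node(n, "characteristic")
    for i, (u, v) in enumerate(edges):
        w = weights[i] if weights is not None else 1.0
        net.add_edge(str(u), str(v), w, accumulate=False)
    return net


def random_er_graph(rng, n, p=0.5, require_edge=True) -> Network:
    while True:
        edges = [
            (i, j) for i, j in itertools.combinations(range(n), 2)
            if rng.random() < p
        ]
        if edges or not require_edge:
            return make_graph(edges, n_nodes=n)


@pytest.fixture(scope="session")
def cohort_24k():
    """Full-size default cohort, generated once per session."""
    config = fn.default_config(24000, 1)
    registry, discharges = fn.generate_cohort(config)
    return config, registry, discharges


@pytest.fixture()
def one_patient_table() -> FeatureTable:
    """The worked toy: one 90+ widowed woman living alone, frail."""
    return make_feature_table(
        [
            {
                "patient_id": "P1",
                "age_class": "90+",
                "gender": "Female",
                "marital_status": "Widowed",
                "family_status": "LivingAlone",
                "frailty_status": "FR",
            }
        ]
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_degree(net: Network) -> dict[str, float]:
    nodes = net.nodes()
    return {
        u: float(sum(1 for v in nodes if v != u and net.weight(u, v) > 0))
        for u in nodes
    }


def brute_pagerank(net: Network, damping=0.85) -> dict[str, float]:
    """Dense linear solve of the teleported random-walk stationarity."""
    nodes = sorted(net.nodes())
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    A = np.zeros((n, n))
    for u, v, w in net.edges():
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    s = A.sum(axis=1)
    M = np.zeros((n, n))
    for j in range(n):
        M[:, j] = 1.0 / n if s[j] == 0 else A[:, j] / s[j]
    x = np.linalg.solve(np.eye(n) - damping * M, np.full(n, (1 - damping) / n))
    x /= x.sum()
    return {u: float(x[idx[u]]) for u in nodes}


def brute_betweenness(net: Network) -> dict[str, float]:
    """Exhaustive simple-path census (endpoints excluded, pairs counted once)."""
    nodes = sorted(net.nodes())
    adj = {u: [v for v in nodes if v != u and net.weight(u, v) > 0] for u in nodes}
    bc = dict.fromkeys(nodes, 0.0)

    def all_paths(s, t):
        out, stack = [], [(s, [s])]
        while stack:
            v, path = stack.pop()
            if v == t:
                out.append(path)
                continue
            for w in adj[v]:
                if w not in path:
                    stack.append((w, path + [w]))
        return out

    for s, t in itertools.combinations(nodes, 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        sp = [p for p in paths if len(p) == shortest]
        for v in nodes:
            if v in (s, t):
                continue
            bc[v] += sum(v in p for p in sp) / len(sp)
    return bc


def set_partitions(items: list):
    """All partitions of ``items`` into non-empty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def exhaustive_best_modularity(net: Network) -> float:
    from frailnet.community import Partition

    return max(
        fn.modularity(
            net, Partition({n: i for i, blk in enumerate(p) for n in blk})
        )
        for p in set_partitions(net.nodes())
    )


def binomial_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / n))
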