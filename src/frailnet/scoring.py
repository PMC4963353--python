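"""Decile-rank scoring of centrality distributions.

Each centrality distribution is split into tenths over the node population
and every node receives an integer score 1-10 per measure (10 = most
influential).  The three scores are summed (maximum potential total 30) and
each node's deviation from that maximum, ``30 - total``, measures how far it
sits from the most central profile.  Communities are compared by the mean
deviation of their modality (characteristic and frailty) nodes.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .centrality import CentralityVector
from .community import Partition
from .graph_model import Network

__all__ = ["decile_score", "total_scores", "community_average_deviation"]

MAX_TOTAL = 30  # 3 measures x top decile score 10
MAX_DEVIATION = MAX_TOTAL - 3


def decile_score(values: CentralityVector | dict) -> dict[str, int]:
    """Empirical-CDF decile score per node.

    ``score(v) = min(10, 1 + floor(10 * #{u: value_u < value_v} / N))`` —
    ties share a score and scores are monotone in the underlying value.
    """
    vals = values.values if isinstance(values, CentralityVector) else dict(values)
    if not vals:
        raise ValueError("empty centrality vector")
    nodes = list(vals)
    arr = np.array([vals[n] for n in nodes], dtype=float)
    order = np.sort(arr)
    below = np.searchsorted(order, arr, side="left")  # strict predecessors
    scores = np.minimum(10, 1 + (10 * below) // len(arr))
    return {n: int(s) for n, s in zip(nodes, scores)}


def total_scores(
    deg_scores: dict[str, int],
    pr_scores: dict[str, int],
    btw_scores: dict[str, int],
) -> pd.DataFrame:
    """Combine the three per-measure scores into the score table.

    Returns a DataFrame indexed by node with columns ``degree_score``,
    ``pagerank_score``, ``betweenness_score``, ``total`` and ``deviation``.
    """
    keys = set(deg_scores)
    if set(pr_scores) != keys or set(btw_scores) != keys:
        raise ValueError("the three score mappings cover different node sets")
    nodes = sorted(keys)
    df = pd.DataFrame(
        {
            "degree_score": [deg_scores[n] for n in nodes],
            "pagerank_score": [pr_scores[n] for n in nodes],
            "betweenness_score": [btw_scores[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    df["total"] = df.sum(axis=1)
    df["deviation"] = MAX_TOTAL - df["total"]
    return df


def community_average_deviation(
    scores: pd.DataFrame, partition: Partition, net: Network
) -> pd.Series:
    """Mean deviation over each community's modality nodes.

    Patient nodes are excluded: the comparison is between the centrality
    profiles of the characteristics (and frailty statuses) gathered in each
    community.  Communities containing no modality node yield NaN.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for node in net.nodes():
        if net.kind[node] == "patient":
            continue
        c = partition[node]
        sums[c] = sums.get(c, 0.0) + float(scores.loc[node, "deviation"])
        counts[c] = counts.get(c, 0) + 1
    labels = sorted(set(partition.membership.values()))
    data = {
        c: (sums[c] / counts[c]) if counts.get(c) else math.nan for c in labels
    }
    return pd.Series(data, name="average_deviation")
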