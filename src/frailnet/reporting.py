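"""Result surfaces: prevalence tables, community composition, profiles.

This module turns the fitted network objects back into the epidemiological
summaries of interest — how each frailty status distributes over the
detected communities, which community each modality joined, and the
multi-morbidity profile prevalences overall and within a community — and
chains the whole pipeline end to end.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import vocab
from .centrality import betweenness, degree, pagerank
from .community import Partition, louvain
from .graph_model import Network, build_network, export_network
from .record_linkage import CategoryMap, FeatureTable, link
from .scoring import community_average_deviation, decile_score, total_scores
from .synthetic_cohort import CohortConfig, generate_cohort, summarize_margins

logger = logging.getLogger("frailnet")

__all__ = [
    "AnalysisReport",
    "community_composition",
    "multimorbidity_profiles",
    "run_pipeline",
]


def community_composition(
    table: FeatureTable, partition: Partition
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Cross-tabulate patients' communities against frailty status.

    Returns ``(by_status, by_community, modality_assignment)``:

    - ``by_status``: row-percentages — of each frailty status's patients,
      the share found in each community (rows sum to 100).
    - ``by_community``: column-normalized variant — the frailty mix within
      each community.
    - ``modality_assignment``: community label of every non-patient node
      present in the partition.
    """
    missing = set(table["patient_id"]) - set(partition.membership)
    if missing:
        raise ValueError(f"partition misses {len(missing)} patient nodes")
    comm = table["patient_id"].map(partition.membership)
    counts = pd.crosstab(table["frailty_status"], comm)
    counts = counts.reindex(list(vocab.FRAILTY_STATUSES)).fillna(0)
    counts.index.name = "frailty_status"
    counts.columns.name = "community"
    by_status = counts.div(counts.sum(axis=1), axis=0) * 100.0
    by_community = counts.div(counts.sum(axis=0), axis=1) * 100.0
    patient_ids = set(table["patient_id"])
    modality_assignment = {
        n: c for n, c in partition.membership.items() if n not in patient_ids
    }
    return by_status, by_community, modality_assignment


def multimorbidity_profiles(
    table: FeatureTable,
    subgroup: int | None = None,
    partition: Partition | None = None,
) -> tuple[pd.DataFrame, float]:
    """Profile prevalences per frailty status, and the prevalence ratio.

    A profile is the exact set of flagged clinical categories of a
    hospitalized patient carrying at least two flags.  Prevalences are
    percentages of each frailty status's population (within ``subgroup``
    when given, which requires ``partition``).  The second return value is
    the ratio, in percent, of the subgroup's overall multi-morbidity
    proportion to the full table's (100.0 when no subgroup is given).
    """
    categories = list(getattr(table, "category_names", vocab.CLINICAL_CATEGORIES))

    def mm_mask(t: pd.DataFrame) -> pd.Series:
        return t["hospitalized"] & (t[categories].sum(axis=1) >= 2)

    overall_prop = float(mm_mask(table).mean())

    sub = table
    if subgroup is not None:
        if partition is None:
            raise ValueError("subgroup selection requires a partition")
        labels = set(partition.membership.values())
        if subgroup not in labels:
            raise ValueError(f"unknown community label {subgroup!r}")
        member = table["patient_id"].map(partition.membership) == subgroup
        sub = table[member]

    names = [name for name, _ in vocab.NAMED_PROFILES] + [vocab.OTHER_PROFILE_LABEL]
    out = pd.DataFrame(0.0, index=names, columns=list(vocab.FRAILTY_STATUSES))
    status_n = sub["frailty_status"].value_counts()
    flags = sub[categories].to_numpy(dtype=bool)
    mm = mm_mask(sub).to_numpy()
    statuses = sub["frailty_status"].to_numpy()
    for i in range(len(sub)):
        if not mm[i]:
            continue
        profile = frozenset(c for c, f in zip(categories, flags[i]) if f)
        out.loc[vocab.profile_name(profile), statuses[i]] += 1
    for f in vocab.FRAILTY_STATUSES:
        n = int(status_n.get(f, 0))
        out[f] = out[f] / n * 100.0 if n else float("nan")

    sub_prop = float(mm_mask(sub).mean()) if len(sub) else float("nan")
    ratio = 100.0 * sub_prop / overall_prop if overall_prop > 0 else float("nan")
    return out, ratio


@dataclasses.dataclass
class AnalysisReport:
    """Everything the end-to-end run produces, ready for serialization."""

    n_patients: int
    seed: int
    n_nodes: int
    n_edges: int
    modularity: float
    n_communities: int
    margins: "pd.DataFrame"
    composition_by_status: pd.DataFrame
    composition_by_community: pd.DataFrame
    modality_assignment: dict[str, int]
    community_sizes: pd.Series
    average_deviation: pd.Series
    profiles_overall: pd.DataFrame
    provenance: dict

    def to_json(self) -> str:
        payload = {
            "n_patients": self.n_patients,
            "seed": self.seed,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "modularity": self.modularity,
            "n_communities": self.n_communities,
            "margins": json.loads(self.margins.to_json()),
            "composition_by_status": json.loads(
                self.composition_by_status.to_json()),
            "composition_by_community": json.loads(
                self.composition_by_community.to_json()),
            "modality_assignment": self.modality_assignment,
            "community_sizes": json.loads(self.community_sizes.to_json()),
            "average_deviation": json.loads(self.average_deviation.to_json()),
            "profiles_overall": json.loads(self.profiles_overall.to_json()),
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def run_pipeline(
    config: CohortConfig,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    compute_betweenness: bool = True,
    deciles_over: str = "modalities",
) -> AnalysisReport:
    """Simulate, link, build, measure, cluster, score and report.

    ``seed`` overrides the config seed for both generation and the
    community-detection sweep order.  When ``out_dir`` is given, all
    intermediate delimited-text files, the GEXF export and the JSON report
    are written there.  ``deciles_over`` selects the population the decile
    cut-points are computed on: the ``"modalities"`` (default) or ``"all"``
    nodes including patients.  The default scores each characteristic
    against the other characteristics: modality nodes are connection hubs,
    so against the whole node population they would all collapse into the
    top decile and every deviation would read 0.
    """
    if deciles_over not in ("all", "modalities"):
        raise ValueError("deciles_over must be 'all' or 'modalities'")
    if seed is not None:
        config = config.replace(seed=int(seed))
    seed = config.seed

    logger.info("simulate: n=%d seed=%d", config.n_patients, seed)
    registry, discharges = generate_cohort(config)

    logger.info("link: %d discharges", len(discharges))
    cmap = CategoryMap(
        entries={
            root: cat
            for cat, roots in config.codes_per_category.items()
            for root in roots
        }
    )
    import datetime as _dt

    window = (
        config.index_date - _dt.timedelta(days=config.window_days),
        config.index_date,
    )
    table = link(registry, discharges, cmap, window)

    logger.info("build network")
    net = build_network(table)

    logger.info("centralities (betweenness=%s)", compute_betweenness)
    deg = degree(net)
    pr = pagerank(net)
    measures = {"degree": deg, "pagerank": pr}
    if compute_betweenness:
        measures["betweenness"] = betweenness(net)

    logger.info("communities (louvain, seed=%d)", seed)
    partition, q = louvain(net, seed=seed)

    logger.info("scores")
    modality_nodes = [n for n in net.nodes() if net.kind[n] != "patient"]

    def _score(cv):
        if deciles_over == "modalities":
            return decile_score({n: cv.values[n] for n in modality_nodes})
        return decile_score(cv)

    per_measure = {name: _score(cv) for name, cv in measures.items()}
    if "betweenness" not in per_measure:
        # without betweenness the 3-measure total is not defined; reuse the
        # degree ranking so totals stay comparable but flag it in provenance
        per_measure["betweenness"] = dict(per_measure["degree"])
    scores = total_scores(
        per_measure["degree"], per_measure["pagerank"], per_measure["betweenness"]
    )
    score_nodes = set(scores.index)
    # patient nodes are excluded inside; the score table always covers the
    # modality nodes whichever decile population was used
    avg_dev = community_average_deviation(scores, partition, net)

    logger.info("report")
    margins = summarize_margins(registry, discharges, cmap).to_frame()
    by_status, by_community, assignment = community_composition(table, partition)
    profiles, _ = multimorbidity_profiles(table)
    sizes = (
        table["patient_id"].map(partition.membership).value_counts().sort_index()
    )
    sizes.name = "n_patients"

    provenance = {
        "seed": seed,
        "n_patients": config.n_patients,
        "coverage_attempt": registry.attrs.get("attempt"),
        "pagerank_params": pr.params,
        "betweenness_computed": compute_betweenness,
        "deciles_over": deciles_over,
        "resolution": 1.0,
    }

    report = AnalysisReport(
        n_patients=config.n_patients,
        seed=seed,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        modularity=q,
        n_communities=partition.n_communities,
        margins=margins,
        composition_by_status=by_status,
        composition_by_community=by_community,
        modality_assignment=assignment,
        community_sizes=sizes,
        average_deviation=avg_dev,
        profiles_overall=profiles,
        provenance=provenance,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        registry.to_csv(out / "registry.csv", index=False)
        discharges.to_csv(out / "discharges.csv", index=False)
        cmap.to_file(out / "category_map.csv")
        pd.DataFrame(table).to_csv(out / "feature_table.csv", index=False)
        for node in net.nodes():
            net.node_attrs[node]["community"] = partition[node]
            if node in score_nodes:
                net.node_attrs[node].update(
                    degree=deg.values[node],
                    pagerank=pr.values[node],
                    total_score=int(scores.loc[node, "total"]),
                    deviation=int(scores.loc[node, "deviation"]),
                )
        export_network(net, "gexf", out / "network.gexf")
        export_network(net, "csv", out / "network_csv")
        scores.to_csv(out / "scores.csv")
        (out / "report.json").write_text(report.to_json(), encoding="utf-8")
        config.to_yaml(out / "config.yaml")
        (out / "provenance.json").write_text(
            json.dumps(provenance, indent=2, sort_keys=True), encoding="utf-8"
        )
    return report
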