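"""The undirected patient-characteristic co-occurrence network.

One node per patient, one node per observed modality (socio-demographic
level, clinical category or frailty status); each patient connects to every
modality it carries, and two modality nodes are connected whenever they
co-occur in the same patient, with the edge weight counting such patients.
Patient-patient edges never exist.

The graph container is deliberately minimal (dict-of-dict adjacency with
node kinds); third-party graph libraries are used in the test suite as
independent oracles, not here.
"""

from __future__ import annotations

import csv
import itertools
from collections import Counter
from pathlib import Path
from xml.etree import ElementTree as ET

from . import vocab

__all__ = ["Network", "build_network", "export_network", "import_network_csv"]

NODE_KINDS = ("patient", "characteristic", "frailty")


class Network:
    """Undirected weighted simple graph with typed nodes."""

    def __init__(self) -> None:
        self.kind: dict[str, str] = {}
        self.label: dict[str, str] = {}
        self.node_attrs: dict[str, dict] = {}
        self._adj: dict[str, dict[str, float]] = {}

    # -- construction ------------------------------------------------------

    def add_node(self, node_id: str, kind: str, label: str | None = None) -> None:
        if kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {kind!r}")
        if node_id not in self._adj:
            self._adj[node_id] = {}
            self.node_attrs[node_id] = {}
        self.kind[node_id] = kind
        self.label[node_id] = label if label is not None else node_id

    def add_edge(self, u: str, v: str, weight: float = 1.0,
                 accumulate: bool = True) -> None:
        if u == v:
            raise ValueError("self-loops are not allowed")
        for x in (u, v):
            if x not in self._adj:
                raise KeyError(f"unknown node {x!r}")
        if self.kind[u] == "patient" and self.kind[v] == "patient":
            raise ValueError("patient-patient edges are not allowed")
        w = self._adj[u].get(v, 0.0) + weight if accumulate else weight
        self._adj[u][v] = w
        self._adj[v][u] = w

    # -- queries -----------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._adj

    def nodes(self) -> list[str]:
        return list(self._adj)

    def neighbors(self, u: str):
        return self._adj[u].items()

    def degree(self, u: str) -> int:
        return len(self._adj[u])

    def strength(self, u: str) -> float:
        return float(sum(self._adj[u].values()))

    def weight(self, u: str, v: str) -> float:
        return self._adj[u].get(v, 0.0)

    def edges(self):
        """Iterate (u, v, weight) with u < v exactly once per edge."""
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                if u < v:
                    yield u, v, w

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.edges())

    def copy(self) -> "Network":
        out = Network()
        for n in self._adj:
            out.add_node(n, self.kind[n], self.label[n])
            out.node_attrs[n] = dict(self.node_attrs[n])
        for u, v, w in self.edges():
            out.add_edge(u, v, w, accumulate=False)
        return out


def _row_modalities(row, category_names) -> list[str]:
    mods = [
        vocab.AGE_LABELS[row["age_class"]],
        row["gender"],
        row["marital_status"],
        row["family_status"],
        vocab.FRAILTY_LABELS[row["frailty_status"]],
    ]
    mods.extend(c for c in category_names if row[c])
    return mods


def build_network(table, unweighted: bool = False) -> Network:
    """Build the co-occurrence network from a feature table.

    Modality nodes are created only for observed modalities, so the node
    count is ``n_patients + n_observed_modalities`` (32 modality nodes for a
    full cohort: 28 characteristics + 4 frailty statuses).  With
    ``unweighted=True`` all co-occurrence weights collapse to 1.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    category_names = getattr(table, "category_names", vocab.CLINICAL_CATEGORIES)
    frailty_nodes = set(vocab.FRAILTY_LABELS.values())

    net = Network()
    pair_counts: Counter[tuple[str, str]] = Counter()
    for _, row in table.iterrows():
        pid = row["patient_id"]
        mods = _row_modalities(row, category_names)
        net.add_node(pid, "patient")
        for m in mods:
            if m not in net:
                net.add_node(
                    m, "frailty" if m in frailty_nodes else "characteristic"
                )
            net.add_edge(pid, m, 1.0, accumulate=False)
        for a, b in itertools.combinations(sorted(mods), 2):
            pair_counts[(a, b)] += 1

    for (a, b), count in sorted(pair_counts.items()):
        net.add_edge(a, b, 1.0 if unweighted else float(count), accumulate=False)
    return net


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_GEXF_NS = "http://gexf.net/1.3"


def _attr_columns(net: Network) -> list[str]:
    cols: list[str] = []
    for attrs in net.node_attrs.values():
        for k in attrs:
            if k not in cols:
                cols.append(k)
    return cols


def export_network(net: Network, fmt: str, path) -> list[Path]:
    """Serialize ``net`` as GEXF 1.3, GraphML, or a nodes/edges CSV pair.

    For ``fmt="csv"``, ``path`` is a directory that will receive
    ``nodes.csv`` and ``edges.csv``; otherwise it is the output file.  Any
    node attributes previously attached (community, centralities, scores)
    are exported alongside ``kind`` and ``label``.
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "csv":
        path.mkdir(parents=True, exist_ok=True)
        extra = _attr_columns(net)
        nodes_p, edges_p = path / "nodes.csv", path / "edges.csv"
        with open(nodes_p, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "kind", "label", *extra])
            for n in sorted(net.nodes()):
                w.writerow([n, net.kind[n], net.label[n],
                            *[net.node_attrs[n].get(k, "") for k in extra]])
        with open(edges_p, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target", "weight"])
            for u, v, wt in sorted(net.edges()):
                w.writerow([u, v, wt])
        return [nodes_p, edges_p]
    if fmt == "gexf":
        _write_gexf(net, path)
        return [path]
    if fmt == "graphml":
        _write_graphml(net, path)
        return [path]
    raise ValueError(f"unknown format {fmt!r} (use gexf, graphml or csv)")


def _write_gexf(net: Network, path: Path) -> None:
    ET.register_namespace("", _GEXF_NS)
    root = ET.Element(f"{{{_GEXF_NS}}}gexf", version="1.3")
    graph = ET.SubElement(root, f"{{{_GEXF_NS}}}graph",
                          defaultedgetype="undirected", mode="static")
    extra = _attr_columns(net)
    attributes = ET.SubElement(graph, f"{{{_GEXF_NS}}}attributes",
                               attrib={"class": "node"})
    attr_ids = {"kind": "0"}
    ET.SubElement(attributes, f"{{{_GEXF_NS}}}attribute",
                  id="0", title="kind", type="string")
    for i, name in enumerate(extra, start=1):
        attr_ids[name] = str(i)
        sample = next(
            (net.node_attrs[n][name] for n in net.nodes()
             if name in net.node_attrs[n]), "")
        a_type = ("integer" if isinstance(sample, (int,)) and not isinstance(sample, bool)
                  else "double" if isinstance(sample, float) else "string")
        ET.SubElement(attributes, f"{{{_GEXF_NS}}}attribute",
                      id=str(i), title=name, type=a_type)
    nodes_el = ET.SubElement(graph, f"{{{_GEXF_NS}}}nodes")
    for n in sorted(net.nodes()):
        node_el = ET.SubElement(nodes_el, f"{{{_GEXF_NS}}}node",
                                id=n, label=net.label[n])
        values = ET.SubElement(node_el, f"{{{_GEXF_NS}}}attvalues")
        ET.SubElement(values, f"{{{_GEXF_NS}}}attvalue",
                      **{"for": "0", "value": net.kind[n]})
        for name in extra:
            if name in net.node_attrs[n]:
                ET.SubElement(values, f"{{{_GEXF_NS}}}attvalue",
                              **{"for": attr_ids[name],
                                 "value": str(net.node_attrs[n][name])})
    edges_el = ET.SubElement(graph, f"{{{_GEXF_NS}}}edges")
    for i, (u, v, w) in enumerate(sorted(net.edges())):
        ET.SubElement(edges_el, f"{{{_GEXF_NS}}}edge",
                      id=str(i), source=u, target=v, weight=str(w))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def _write_graphml(net: Network, path: Path) -> None:
    ns = "http://graphml.graphdrawing.org/xmlns"
    ET.register_namespace("", ns)
    root = ET.Element(f"{{{ns}}}graphml")
    extra = ["kind", "label", *_attr_columns(net)]
    for i, name in enumerate(extra):
        ET.SubElement(root, f"{{{ns}}}key", id=f"d{i}",
                      **{"for": "node", "attr.name": name, "attr.type": "string"})
    ET.SubElement(root, f"{{{ns}}}key", id="w",
                  **{"for": "edge", "attr.name": "weight", "attr.type": "double"})
    graph = ET.SubElement(root, f"{{{ns}}}graph", edgedefault="undirected")
    for n in sorted(net.nodes()):
        node_el = ET.SubElement(graph, f"{{{ns}}}node", id=n)
        data = {"kind": net.kind[n], "label": net.label[n], **net.node_attrs[n]}
        for i, name in enumerate(extra):
            if name in data:
                d = ET.SubElement(node_el, f"{{{ns}}}data", key=f"d{i}")
                d.text = str(data[name])
    for u, v, w in sorted(net.edges()):
        e = ET.SubElement(graph, f"{{{ns}}}edge", source=u, target=v)
        d = ET.SubElement(e, f"{{{ns}}}data", key="w")
        d.text = str(w)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="utf-8", xml_declaration=True)


def import_network_csv(path) -> Network:
    """Rebuild a network from an exported nodes.csv/edges.csv pair."""
    path = Path(path)
    net = Network()
    with open(path / "nodes.csv", newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        extra = [c for c in (reader.fieldnames or [])
                 if c not in ("id", "kind", "label")]
        for row in reader:
            net.add_node(row["id"], row["kind"], row["label"])
            for k in extra:
                if row[k] != "":
                    net.node_attrs[row["id"]][k] = row[k]
    with open(path / "edges.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            net.add_edge(row["source"], row["target"], float(row["weight"]),
                         accumulate=False)
    return net
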