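"""Multilayer network assembly, subnetwork extraction, modules, centrality, export.

The assembled object is a typed-node, typed-edge graph merging four layers:

* signed gene–gene co-expression (undirected; ``coexpression_pos`` /
  ``coexpression_neg``, weight = r)
* TF co-expression: positive gene–gene edges with exactly one endpoint in a
  user-supplied transcription-factor list are re-typed as directed
  ``tf_coexpression`` TF→target edges — a readability convention; the
  underlying correlation is symmetric and recoverable from the weight
* lncRNA–gene co-location (undirected ``lncrna_colocation``, weight = r)
* miRNA→gene targeting (directed ``mirna_target``, weight = expectation)

Node types: enzyme_gene | TF | lncRNA | miRNA. Modules are detected on the
positive-correlation subgraph (connected components by default, or greedy
modularity on |weight|); negative edges never join modules but remain as
between-module links. Exports: GraphML, SIF (edge_type as the interaction
token), and node/edge TSV tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .colocation import ColocationPair
from .gcn import CoexpressionEdge

logger = logging.getLogger(__name__)

EDGE_TYPES = {
    "coexpression_pos",
    "coexpression_neg",
    "tf_coexpression",
    "mirna_target",
    "lncrna_colocation",
}
NODE_TYPES = {"enzyme_gene", "TF", "lncRNA", "miRNA"}
DIRECTED_TYPES = {"tf_coexpression", "mirna_target"}
POSITIVE_TYPES = {"coexpression_pos", "tf_coexpression"}


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    edge_type: str
    weight: float

    def __post_init__(self) -> None:
        if self.edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge_type {self.edge_type!r}")

    @property
    def directed(self) -> bool:
        return self.edge_type in DIRECTED_TYPES

    def key(self) -> tuple:
        if self.directed:
            return (self.a, self.b, self.edge_type)
        return (*sorted((self.a, self.b)), self.edge_type)


@dataclass
class MultilayerNetwork:
    """Typed nodes (id → attribute dict) plus a typed edge list."""

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[Edge] = field(default_factory=list)

    def add_node(self, node_id: str, node_type: str, **annotations) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node_type {node_type!r}")
        if node_id in self.nodes:
            self.nodes[node_id].update(annotations)
        else:
            self.nodes[node_id] = {"node_type": node_type, **annotations}

    def add_edge(self, a: str, b: str, edge_type: str, weight: float) -> None:
        missing = [x for x in (a, b) if x not in self.nodes]
        if missing:
            raise ValueError(f"edge endpoints absent from node table: {missing}")
        self.edges.append(Edge(a, b, edge_type, float(weight)))

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges, key=lambda e: e.key())

    def to_networkx(self) -> nx.MultiDiGraph:
        """Directed multigraph view: undirected edges stored once a→b (a<b)."""
        g = nx.MultiDiGraph()
        for nid in sorted(self.nodes):
            g.add_node(nid, **self.nodes[nid])
        for e in self.sorted_edges():
            a, b = (e.a, e.b) if e.directed else sorted((e.a, e.b))
            g.add_edge(a, b, edge_type=e.edge_type, weight=e.weight,
                       directed=e.directed)
        return g


def assemble(
    gcn_edges: list[CoexpressionEdge],
    tf_list: list[str] | None = None,
    lncrna_edges: list[ColocationPair] | None = None,
    mirna_edge_table: pd.DataFrame | None = None,
    annotations: dict[str, dict] | None = None,
) -> MultilayerNetwork:
    """Merge all layers into one network; nothing is dropped silently.

    Positive co-expression edges with exactly one endpoint in ``tf_list``
    become directed TF→target ``tf_coexpression`` edges (TF–TF pairs stay
    undirected co-expression). ``annotations`` (e.g. motif presence, pathway
    label, lncRNA relation) are attached per node id. Identifier collisions
    across layers (one id claimed with two node types) get type prefixes and
    a log line.
    """
    tfs = set(tf_list or [])
    net = MultilayerNetwork()

    def claim(node_id: str, node_type: str) -> str:
        existing = net.nodes.get(node_id)
        if existing is not None and existing["node_type"] != node_type:
            new_id = f"{node_type.lower()}:{node_id}"
            logger.warning(
                "id collision: %s is both %s and %s; using %s",
                node_id, existing["node_type"], node_type, new_id,
            )
            node_id = new_id
        net.add_node(node_id, node_type)
        return node_id

    def gene_type(gid: str) -> str:
        return "TF" if gid in tfs else "enzyme_gene"

    n_retyped = 0
    for e in gcn_edges:
        a = claim(e.gene_a, gene_type(e.gene_a))
        b = claim(e.gene_b, gene_type(e.gene_b))
        a_tf, b_tf = e.gene_a in tfs, e.gene_b in tfs
        if e.sign == "positive" and a_tf != b_tf:
            src, dst = (a, b) if a_tf else (b, a)
            net.add_edge(src, dst, "tf_coexpression", e.r)
            n_retyped += 1
        else:
            etype = "coexpression_pos" if e.sign == "positive" else "coexpression_neg"
            net.add_edge(a, b, etype, e.r)
    if n_retyped:
        logger.info("assemble: %d co-expression edges re-typed TF->target", n_retyped)
    for p in lncrna_edges or []:
        lnc = claim(p.lncrna_id, "lncRNA")
        g = claim(p.gene_id, gene_type(p.gene_id))
        net.nodes[lnc].setdefault("relation", p.relation)
        net.add_edge(lnc, g, "lncrna_colocation", p.r)
    if mirna_edge_table is not None:
        for _, row in mirna_edge_table.iterrows():
            m = claim(str(row["mirna"]), "miRNA")
            g = claim(str(row["gene"]), gene_type(str(row["gene"])))
            net.add_edge(m, g, "mirna_target", float(row["expectation"]))
    for nid, ann in (annotations or {}).items():
        if nid in net.nodes:
            net.nodes[nid].update(ann)
        else:
            logger.info("annotation for absent node %s ignored", nid)
    return net


def extract_subnetwork(
    net: MultilayerNetwork,
    pathway_genes: list[str],
    include_regulators: bool = True,
) -> MultilayerNetwork:
    """Pathway-focused view: induced subgraph plus (optionally) regulators.

    With ``include_regulators``, every TF, miRNA, or lncRNA with at least
    one edge to a pathway gene is pulled in along with those edges. Pathway
    ids absent from the network are warned about, not fatal.
    """
    missing = [g for g in pathway_genes if g not in net.nodes]
    if missing:
        logger.warning("extract_subnetwork: %d pathway ids absent", len(missing))
    keep = {g for g in pathway_genes if g in net.nodes}
    if include_regulators:
        for e in net.edges:
            for reg, other in ((e.a, e.b), (e.b, e.a)):
                if other in keep and net.nodes[reg]["node_type"] in (
                    "TF", "miRNA", "lncRNA",
                ):
                    keep.add(reg)
    sub = MultilayerNetwork()
    for nid in sorted(keep):
        sub.nodes[nid] = dict(net.nodes[nid])
    for e in net.edges:
        if e.a in keep and e.b in keep:
            sub.edges.append(e)
    for g in pathway_genes:
        if g in sub.nodes:
            sub.nodes[g]["pathway"] = True
    return sub


@dataclass
class ModulePartition:
    """Node → module label, with the method and seed that produced it."""

    labels: dict[str, str]
    method: str
    seed: int


def detect_modules(
    net: MultilayerNetwork, method: str = "positive_components", seed: int = 0
) -> ModulePartition:
    """Partition nodes into co-expression modules.

    ``positive_components``: connected components of the subgraph restricted
    to positive-correlation edge types; negative edges never merge modules
    (they remain between-module links). ``greedy_modularity``: networkx
    greedy modularity maximization on |weight| over all edges. Labels are
    deterministic: components sorted by their lexicographically smallest
    member and named M1, M2, …; every node (including isolates) is labeled.
    """
    if method == "positive_components":
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        for e in net.edges:
            if e.edge_type in POSITIVE_TYPES:
                g.add_edge(e.a, e.b)
        comps = [sorted(c) for c in nx.connected_components(g)]
    elif method == "greedy_modularity":
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        for e in net.edges:
            w = abs(e.weight)
            if g.has_edge(e.a, e.b):
                g[e.a][e.b]["weight"] += w
            else:
                g.add_edge(e.a, e.b, weight=w)
        comps = [sorted(c) for c in
                 nx.algorithms.community.greedy_modularity_communities(g, weight="weight")]
    else:
        raise ValueError(f"unknown module detection method {method!r}")
    comps.sort(key=lambda c: c[0])
    labels = {n: f"M{i + 1}" for i, comp in enumerate(comps) for n in comp}
    return ModulePartition(labels, method, seed)


def centrality_report(net: MultilayerNetwork) -> pd.DataFrame:
    """Per-node degree by edge type plus total, hubs first.

    Degree counts edge endpoints: an undirected edge contributes 1 to each
    endpoint; a directed edge contributes out-degree 1 to its source and
    in-degree 1 to its target (both tallied in the same type column), so the
    grand total obeys the handshake identity. Sorted by total descending,
    ties broken lexicographically by node id.
    """
    cols = sorted(EDGE_TYPES)
    deg = pd.DataFrame(0, index=sorted(net.nodes), columns=cols)
    for e in net.edges:
        deg.loc[e.a, e.edge_type] += 1
        deg.loc[e.b, e.edge_type] += 1
    deg["total"] = deg[cols].sum(axis=1)
    deg["node_type"] = [net.nodes[n]["node_type"] for n in deg.index]
    order = sorted(deg.index, key=lambda n: (-deg.loc[n, "total"], n))
    deg = deg.loc[order]
    deg.index.name = "node"
    return deg


def _stringify(value):
    if isinstance(value, bool):
        return str(value).lower()
    return value


def export(net: MultilayerNetwork, fmt: str, path) -> None:
    """Write the network as GraphML, SIF, or paired node/edge TSV tables.

    GraphML round-trips node and edge attributes (via networkx); SIF lines
    read ``a <edge_type> b``; ``tsv`` writes ``<path>.nodes.tsv`` and
    ``<path>.edges.tsv``. Output ordering is deterministic.
    """
    if fmt == "graphml":
        g = net.to_networkx()
        for _, data in g.nodes(data=True):
            for k in list(data):
                data[k] = _stringify(data[k])
        nx.write_graphml(g, path)
    elif fmt == "sif":
        lines = [f"{e.a}\t{e.edge_type}\t{e.b}" for e in net.sorted_edges()]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "tsv":
        node_rows = []
        all_keys = sorted({k for d in net.nodes.values() for k in d} - {"node_type"})
        for nid in sorted(net.nodes):
            d = net.nodes[nid]
            node_rows.append([nid, d["node_type"]] + [d.get(k, "") for k in all_keys])
        pd.DataFrame(node_rows, columns=["node", "node_type"] + all_keys).to_csv(
            f"{path}.nodes.tsv", sep="\t", index=False
        )
        edge_rows = [
            (e.a, e.b, e.edge_type, e.weight, e.directed) for e in net.sorted_edges()
        ]
        pd.DataFrame(
            edge_rows, columns=["a", "b", "edge_type", "weight", "directed"]
        ).to_csv(f"{path}.edges.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graphml(path) -> MultilayerNetwork:
    """Read a GraphML export back into a MultilayerNetwork."""
    g = nx.read_graphml(path, force_multigraph=True)
    net = MultilayerNetwork()
    for nid, data in g.nodes(data=True):
        attrs = dict(data)
        ntype = attrs.pop("node_type")
        for k, v in list(attrs.items()):
            if v == "true":
                attrs[k] = True
            elif v == "false":
                attrs[k] = False
        net.add_node(nid, ntype, **attrs)
    for a, b, data in g.edges(data=True):
        net.add_edge(a, b, data["edge_type"], data["weight"])
    return net
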