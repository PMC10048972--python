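"""Tripartite compound–target–pathway network and its topology metrics.

The network is undirected and unweighted. Edges run only between the
component and target partitions (a retained compound→target prediction) and
between the target and pathway partitions (pathway membership). The three
node-level metrics reported downstream — degree, closeness and betweenness —
follow the normalisation conventions of Cytoscape's Network Analyzer:

* closeness of node v in a connected component of size m is
  ``(m − 1) / Σ_u d(v, u)`` over the nodes of that component (0 for an
  isolated node);
* betweenness is shortest-path betweenness over unordered pairs excluding
  endpoints, normalised by ``2 / ((n − 1)(n − 2))`` with n the node count of
  the whole graph, so values lie in [0, 1].

Metrics are computed on the whole tripartite graph; screening medians are
taken within a partition (see :mod:`phytonet.screening`).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import DegenerateNetworkError
from .models import GeneSetAnnotation

PARTITIONS = ("component", "target", "pathway")

#: allowed partition pairs for an edge, with the evidence type each carries
_EDGE_KINDS = {
    frozenset({"component", "target"}): "component-target",
    frozenset({"target", "pathway"}): "target-pathway",
}


@dataclass
class TripartiteNetwork:
    """A compounds–targets–pathways graph.

    Wraps an undirected :class:`networkx.Graph` whose nodes carry a
    ``partition`` attribute and whose edges carry an ``evidence`` attribute
    (``component-target`` or ``target-pathway``).
    """

    graph: nx.Graph

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(cls, nodes, edges) -> "TripartiteNetwork":
        """Build from ``(node_id, partition)`` pairs and node-id pair edges."""
        g = nx.Graph()
        for node_id, partition in nodes:
            if partition not in PARTITIONS:
                raise ValueError(f"unknown partition {partition!r} for {node_id!r}")
            if node_id in g.nodes and g.nodes[node_id]["partition"] != partition:
                raise ValueError(f"node id {node_id!r} used in two partitions")
            g.add_node(node_id, partition=partition)
        for u, v in edges:
            g.add_edge(u, v)
        net = cls(g)
        net._annotate_edges()
        net.validate()
        return net

    def _annotate_edges(self):
        for u, v in self.graph.edges:
            kind = frozenset(
                {self.graph.nodes[u]["partition"], self.graph.nodes[v]["partition"]}
            )
            self.graph.edges[u, v]["evidence"] = _EDGE_KINDS.get(kind, "invalid")

    def validate(self) -> None:
        for node, data in self.graph.nodes(data=True):
            if data.get("partition") not in PARTITIONS:
                raise ValueError(f"node {node!r} lacks a valid partition label")
        for u, v in self.graph.edges:
            if u == v:
                raise ValueError(f"self-loop at {u!r}")
            kind = frozenset(
                {self.graph.nodes[u]["partition"], self.graph.nodes[v]["partition"]}
            )
            if kind not in _EDGE_KINDS:
                raise ValueError(
                    f"edge {u!r}–{v!r} connects partitions {sorted(kind)}"
                )

    # -- accessors --------------------------------------------------------

    def nodes(self, partition: str | None = None) -> set:
        if partition is None:
            return set(self.graph.nodes)
        return {
            n for n, d in self.graph.nodes(data=True) if d["partition"] == partition
        }

    def partition_of(self, node) -> str:
        return self.graph.nodes[node]["partition"]

    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    def summary(self) -> dict:
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            **{f"n_{p}s": len(self.nodes(p)) for p in PARTITIONS},
        }


@dataclass(frozen=True)
class NodeMetrics:
    """Topology metrics for one node of the tripartite network."""

    node_id: str
    partition: str
    degree: int
    closeness: float
    betweenness: float


def build_network(
    per_compound_targets: dict,
    selected_terms: list[GeneSetAnnotation],
    effective_targets: set,
) -> TripartiteNetwork:
    """Assemble the tripartite network from filtered evidence.

    Parameters
    ----------
    per_compound_targets
        compound_id → gene set of similarity-filtered target predictions.
    selected_terms
        The curated pathway/term allow-list providing target–pathway edges.
    effective_targets
        Targets retained for the network (e.g. overlap genes covered by the
        selected pathways); a compound–target edge exists iff the target is
        in the compound's filtered set AND in this set.

    Isolated nodes are dropped; an empty edge set raises
    :class:`DegenerateNetworkError`.
    """
    effective = {g.upper() for g in effective_targets}
    edges = []
    for compound_id, genes in per_compound_targets.items():
        for gene in genes:
            gene = gene.upper()
            if gene in effective:
                edges.append((compound_id, gene))
    term_edges = []
    for term in selected_terms:
        for gene in term.genes & effective:
            term_edges.append((term.term_id, gene))
    if not edges and not term_edges:
        raise DegenerateNetworkError("no edges: nothing passed the filters")

    nodes = []
    used = set()
    for compound_id, gene in edges:
        used.add(compound_id)
        used.add(gene)
    for term_id, gene in term_edges:
        used.add(term_id)
        used.add(gene)
    for compound_id in per_compound_targets:
        if compound_id in used:
            nodes.append((compound_id, "component"))
    for gene in effective:
        if gene in used:
            nodes.append((gene, "target"))
    for term in selected_terms:
        if term.term_id in used:
            nodes.append((term.term_id, "pathway"))
    return TripartiteNetwork.from_edges(
        nodes, [(u, v) for u, v in edges] + [(t, g) for t, g in term_edges]
    )


def degree(net: TripartiteNetwork) -> dict:
    """Incident-edge count per node."""
    return dict(net.graph.degree())


def closeness(net: TripartiteNetwork) -> dict:
    """Within-component closeness centrality, (m−1)/Σ d(v,u)."""
    # wf_improved=False is exactly the within-component convention above
    return nx.closeness_centrality(net.graph, wf_improved=False)


def betweenness(net: TripartiteNetwork) -> dict:
    """Endpoint-excluded shortest-path betweenness, scaled by 2/((n−1)(n−2))."""
    n = net.graph.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in net.graph.nodes}
    return nx.betweenness_centrality(net.graph, normalized=True)


def node_metrics(net: TripartiteNetwork) -> list[NodeMetrics]:
    """All three metrics for every node, with its partition label."""
    deg = degree(net)
    clo = closeness(net)
    bet = betweenness(net)
    return [
        NodeMetrics(
            node_id=v,
            partition=net.partition_of(v),
            degree=int(deg[v]),
            closeness=float(clo[v]),
            betweenness=float(bet[v]),
        )
        for v in sorted(net.graph.nodes, key=str)
    ]
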