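"""Domain networks: connected components of significant co-occurrence links.

Each connected component of the significant-link graph is interpreted as one
(partial) biosynthetic gene cluster: its nodes are domain variants predicted
to be physically co-clustered on the same metagenomic DNA.  Components with
fewer than three domain variants are discarded as the minimal reportable
unit.  Sequencing errors and within-population genetic diversity can split a
single biological domain into several near-identical variants inside one
network; ``merge_similar_nodes`` collapses same-domain-type nodes above 90%
identity (single linkage within the network) into their most abundant
representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import networkx as nx

from .linkage import LinkSet
from .variant_table import OccurrenceMatrix, pairwise_identity

__all__ = [
    "DomainNetwork",
    "build_networks",
    "merge_similar_nodes",
    "export_graph",
    "load_graphml",
]

DEFAULT_MIN_SIZE = 3
DEFAULT_MERGE_ID = 0.90


@dataclass
class NetworkNode:
    variant_id: str
    centroid: str
    domain_type: str
    subpools: frozenset
    total_reads: int = 0


@dataclass
class DomainNetwork:
    """One connected component of the significant-link graph."""

    network_id: str
    nodes: dict[str, NetworkNode]
    edges: list[tuple[str, str, float]]  # (a, b, p_adj), a < b
    merged_from: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_ids(self) -> list[str]:
        return sorted(self.nodes)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(network_id=self.network_id)
        for node_id in self.node_ids():
            node = self.nodes[node_id]
            g.add_node(
                node_id,
                centroid=node.centroid,
                domain_type=node.domain_type,
                subpools=",".join(str(s) for s in sorted(node.subpools, key=str)),
                total_reads=node.total_reads,
                merged_from=",".join(self.merged_from.get(node_id, [node_id])),
            )
        for a, b, p_adj in sorted(self.edges):
            g.add_edge(a, b, p_adj=p_adj)
        return g


def build_networks(
    links: LinkSet,
    matrix: Optional[OccurrenceMatrix] = None,
    min_size: int = DEFAULT_MIN_SIZE,
) -> list[DomainNetwork]:
    """Connected components of the significant-link graph, size-filtered.

    Node metadata (centroid, domain type, subpool set, read totals) is drawn
    from ``matrix`` when given.  Component ids are deterministic: each network
    is named after its lexicographically smallest member, and networks are
    returned sorted by that id.
    """
    g = nx.Graph()
    for t in links.significant_links():
        prev = g.get_edge_data(t.variant_a, t.variant_b)
        if prev is None or t.p_adj < prev["p_adj"]:
            g.add_edge(t.variant_a, t.variant_b, p_adj=t.p_adj)

    networks = []
    for component in nx.connected_components(g):
        if len(component) < min_size:
            continue
        members = sorted(component)
        nodes = {}
        for vid in members:
            if matrix is not None and vid in matrix.counts.index:
                row = matrix.counts.loc[vid]
                nodes[vid] = NetworkNode(
                    variant_id=vid,
                    centroid=str(matrix.meta.at[vid, "centroid"]),
                    domain_type=str(matrix.meta.at[vid, "domain_type"]),
                    subpools=frozenset(row.index[row > 0]),
                    total_reads=int(row.sum()),
                )
            else:
                nodes[vid] = NetworkNode(vid, "", "", frozenset())
        edges = sorted(
            (min(a, b), max(a, b), g.edges[a, b]["p_adj"])
            for a, b in g.subgraph(component).edges
        )
        networks.append(
            DomainNetwork(network_id=f"net_{members[0]}", nodes=nodes, edges=edges)
        )
    networks.sort(key=lambda n: n.network_id)
    return networks


def merge_similar_nodes(
    net: DomainNetwork, id_threshold: float = DEFAULT_MERGE_ID
) -> DomainNetwork:
    """Collapse near-identical same-type nodes within a network.

    Nodes of the same domain type whose centroids exceed ``id_threshold``
    global identity are merged transitively (single linkage).  The merged
    node keeps the centroid of the highest-total-read constituent (ties by
    variant id), its subpool set is the union, parallel edges collapse to the
    smallest adjusted p-value, and self edges vanish.  Node and edge counts
    never increase and the network stays connected.
    """
    ids = net.node_ids()
    parent = {v: v for v in ids}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            na, nb = net.nodes[a], net.nodes[b]
            if na.domain_type != nb.domain_type:
                continue
            if pairwise_identity(na.centroid, nb.centroid) > id_threshold:
                parent[find(a)] = find(b)

    groups: dict[str, list[str]] = {}
    for v in ids:
        groups.setdefault(find(v), []).append(v)

    representative = {}
    merged_nodes = {}
    merged_from = {}
    for members in groups.values():
        rep_node = max(
            (net.nodes[m] for m in members),
            key=lambda n: (n.total_reads, n.variant_id),
        )
        rep = rep_node.variant_id
        for m in members:
            representative[m] = rep
        merged_nodes[rep] = NetworkNode(
            variant_id=rep,
            centroid=rep_node.centroid,
            domain_type=rep_node.domain_type,
            subpools=frozenset().union(*(net.nodes[m].subpools for m in members)),
            total_reads=sum(net.nodes[m].total_reads for m in members),
        )
        merged_from[rep] = sorted(members)

    best_edges: dict[tuple[str, str], float] = {}
    for a, b, p_adj in net.edges:
        ra, rb = representative[a], representative[b]
        if ra == rb:
            continue
        key = (min(ra, rb), max(ra, rb))
        if key not in best_edges or p_adj < best_edges[key]:
            best_edges[key] = p_adj
    edges = sorted((a, b, p) for (a, b), p in best_edges.items())
    return DomainNetwork(
        network_id=f"net_{min(merged_nodes)}",
        nodes=merged_nodes,
        edges=edges,
        merged_from=merged_from,
    )


def export_graph(
    nets: Sequence[DomainNetwork], path: Union[str, Path], format: str = "graphml"
) -> Path:
    """Write networks to GraphML, an edge-list TSV, or a node-table TSV.

    Exports are byte-deterministic for identical inputs, and GraphML
    round-trips losslessly through :func:`load_graphml`.
    """
    path = Path(path)
    if format == "graphml":
        g = nx.Graph()
        for net in sorted(nets, key=lambda n: n.network_id):
            sub = net.to_graph()
            for node, data in sub.nodes(data=True):
                g.add_node(node, network_id=net.network_id, **data)
            for a, b, data in sub.edges(data=True):
                g.add_edge(a, b, **data)
        nx.write_graphml(g, path, named_key_ids=True, edge_id_from_attribute=None)
    elif format == "edgelist":
        with open(path, "w") as fh:
            fh.write("network_id\tvariant_a\tvariant_b\tp_adj\n")
            for net in sorted(nets, key=lambda n: n.network_id):
                for a, b, p_adj in sorted(net.edges):
                    fh.write(f"{net.network_id}\t{a}\t{b}\t{p_adj:.6e}\n")
    elif format == "nodes":
        with open(path, "w") as fh:
            fh.write(
                "network_id\tvariant_id\tdomain_type\ttotal_reads\tn_subpools"
                "\tsubpools\tmerged_from\tcentroid\n"
            )
            for net in sorted(nets, key=lambda n: n.network_id):
                for vid in net.node_ids():
                    node = net.nodes[vid]
                    subpools = ",".join(str(s) for s in sorted(node.subpools, key=str))
                    merged = ",".join(net.merged_from.get(vid, [vid]))
                    fh.write(
                        f"{net.network_id}\t{vid}\t{node.domain_type}\t{node.total_reads}"
                        f"\t{len(node.subpools)}\t{subpools}\t{merged}\t{node.centroid}\n"
                    )
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def load_graphml(path: Union[str, Path]) -> list[DomainNetwork]:
    """Rebuild DomainNetworks from a GraphML export."""
    g = nx.read_graphml(path)
    networks = []
    for component in nx.connected_components(g):
        members = sorted(component)
        network_id = g.nodes[members[0]].get("network_id", f"net_{members[0]}")
        nodes = {}
        merged_from = {}
        for vid in members:
            data = g.nodes[vid]
            subpools = data.get("subpools", "")
            nodes[vid] = NetworkNode(
                variant_id=vid,
                centroid=data.get("centroid", ""),
                domain_type=data.get("domain_type", ""),
                subpools=frozenset(s for s in subpools.split(",") if s),
                total_reads=int(data.get("total_reads", 0)),
            )
            merged_from[vid] = data.get("merged_from", vid).split(",")
        edges = sorted(
            (min(a, b), max(a, b), float(g.edges[a, b]["p_adj"]))
            for a, b in g.subgraph(component).edges
        )
        networks.append(
            DomainNetwork(
                network_id=network_id, nodes=nodes, edges=edges, merged_from=merged_from
            )
        )
    networks.sort(key=lambda n: n.network_id)
    return networks
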