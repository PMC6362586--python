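"""Build associative gene networks for a gene set, filter them by tissue, and
build the intermediary network around central nodes.

An associative gene network here is the knowledge-graph subnetwork induced by
a set of seed genes together with their protein products (one expression edge
away).  Tissue filtering keeps the genes with a present expression call in the
tissue; a protein survives iff at least one of its encoding genes survives —
expression calls exist for genes, not proteins, so protein retention follows
the encoding gene.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .kb_model import (
    BioNode,
    ExpressionCatalog,
    Interaction,
    KnowledgeGraph,
    TissueLookupError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneNetwork:
    """A named induced subnetwork with provenance.

    Invariants: edges run only among ``nodes``; every protein node has at
    least one incoming expression edge from a gene node in the network.
    """

    name: str
    nodes: Mapping[str, BioNode]
    edges: tuple[Interaction, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(i for i, n in self.nodes.items() if n.kind == "gene")

    @property
    def protein_ids(self) -> frozenset[str]:
        return frozenset(i for i, n in self.nodes.items() if n.kind == "protein")

    def genes_encoding(self, protein_id: str) -> frozenset[str]:
        return frozenset(
            e.source
            for e in self.edges
            if e.itype == "expression" and e.target == protein_id
        )

    def to_networkx(self) -> nx.MultiDiGraph:
        """Faithful typed view: undirected edges appear as antiparallel pairs."""
        g = nx.MultiDiGraph(name=self.name)
        for nid in sorted(self.nodes):
            node = self.nodes[nid]
            g.add_node(nid, kind=node.kind, symbol=node.symbol)
        for e in self.edges:
            g.add_edge(e.source, e.target, itype=e.itype, directed=e.directed)
            if not e.directed:
                g.add_edge(e.target, e.source, itype=e.itype, directed=e.directed)
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<GeneNetwork {self.name!r}: {self.n_nodes} nodes, {self.n_edges} edges>"


def _induced_edges(kb_edges: Iterable[Interaction], members: set[str]) -> tuple[Interaction, ...]:
    return tuple(e for e in kb_edges if e.source in members and e.target in members)


def induce_network(kb: KnowledgeGraph, genes: Iterable[str], name: str) -> GeneNetwork:
    """Reconstruct the associative gene network of a gene set.

    Nodes are the seed genes found in the knowledge-graph universe plus every
    protein one expression edge downstream of them; edges are all knowledge
    -graph edges with both endpoints inside.  Seed ids absent from the
    universe are logged as warnings, never errors.
    """
    genes = set(genes)
    if not genes:
        raise ValueError("empty gene set")
    known = genes & kb.gene_universe
    unknown = sorted(genes - known)
    if not known:
        raise ValueError("no seed genes found in the knowledge-graph universe")
    if unknown:
        logger.warning(
            "%d seed gene(s) not in the knowledge graph: %s",
            len(unknown),
            ", ".join(unknown[:10]) + ("..." if len(unknown) > 10 else ""),
        )
    members = set(known)
    for e in kb.edges:
        if e.itype == "expression" and e.source in known:
            members.add(e.target)
    nodes = {nid: kb.nodes[nid] for nid in sorted(members)}
    edges = _induced_edges(kb.edges, members)
    return GeneNetwork(
        name,
        nodes,
        edges,
        provenance={"gene_set": name, "tissue": "combined", "n_seed_unknown": len(unknown)},
    )


def filter_by_tissue(
    net: GeneNetwork, catalog: ExpressionCatalog, tissue: str
) -> GeneNetwork:
    """Restrict a network to genes expressed in one tissue.

    Gene nodes with a present call are kept; a protein node is kept iff at
    least one of its encoding genes (within the network) is kept; edges are
    re-induced.  The operation is idempotent and monotone (the result is a
    sub-network of the input).
    """
    matches = catalog.match_tissues(tissue)
    if not matches:
        # surfaces near-miss suggestions
        catalog.genes_expressed_in(tissue.rstrip("*"))
        raise TissueLookupError(tissue, [])
    if len(matches) > 1:
        raise ValueError(
            f"tissue pattern {tissue!r} is ambiguous for filtering: {', '.join(matches)}"
        )
    resolved = matches[0]
    expressed = catalog.genes_expressed_in(resolved)
    kept_genes = net.gene_ids & expressed
    kept: set[str] = set(kept_genes)
    for pid in net.protein_ids:
        if net.genes_encoding(pid) & kept_genes:
            kept.add(pid)
    nodes = {nid: net.nodes[nid] for nid in sorted(kept)}
    edges = _induced_edges(net.edges, kept)
    degenerate = not kept
    if degenerate:
        logger.warning("tissue %r leaves an empty network", resolved)
    return GeneNetwork(
        resolved if net.name == "combined" else f"{net.name}|{resolved}",
        nodes,
        edges,
        provenance={
            "gene_set": net.provenance.get("gene_set", net.name),
            "tissue": resolved,
            "degenerate": degenerate,
        },
    )


def intermediary_network(
    kb: KnowledgeGraph, central: Iterable[str], min_links: int = 2, name: str = "intermediary"
) -> GeneNetwork:
    """Central vertices plus every vertex adjacent to at least ``min_links``
    of them, with induced edges.

    Adjacency ignores edge direction and type: the construct describes
    connectivity around the central nodes, not regulation polarity.
    """
    central = set(central)
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    missing = sorted(c for c in central if c not in kb.nodes)
    if missing:
        raise ValueError(f"unknown central node(s): {', '.join(missing)}")
    adj = kb.adjacency
    members = set(central)
    for v in kb.nodes:
        if v in central:
            continue
        if sum(1 for c in central if c in adj[v]) >= min_links:
            members.add(v)
    nodes = {nid: kb.nodes[nid] for nid in sorted(members)}
    edges = _induced_edges(kb.edges, members)
    return GeneNetwork(
        name,
        nodes,
        edges,
        provenance={"central": tuple(sorted(central)), "min_links": min_links},
    )


def annotate_tissue_codes(
    net: GeneNetwork,
    catalog: ExpressionCatalog,
    tissue_codes: Sequence[tuple[str, str]],
) -> dict[str, str]:
    """Label each node with the codes of the tissues expressing its gene.

    ``tissue_codes`` is an ordered list of (tissue name, short code) pairs;
    codes must be unique.  A gene node gets the comma-joined codes of the
    tissues where it has a present call; a protein node inherits the union of
    its encoding genes' codes.  Returns node id -> label.
    """
    codes = [c for _, c in tissue_codes]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate tissue codes")
    expressed = [(catalog.genes_expressed_in(t), c) for t, c in tissue_codes]
    labels: dict[str, str] = {}
    for gid in net.gene_ids:
        labels[gid] = ",".join(c for genes, c in expressed if gid in genes)
    for pid in net.protein_ids:
        encoding = net.genes_encoding(pid)
        labels[pid] = ",".join(
            c for genes, c in expressed if encoding & genes
        )
    return labels


def write_graphml(
    net: GeneNetwork, path: str | Path, node_labels: Mapping[str, str] | None = None
) -> None:
    """Export a network (optionally with tissue-code labels) as GraphML."""
    g = net.to_networkx()
    if node_labels:
        for nid, label in node_labels.items():
            if nid in g:
                g.nodes[nid]["tissue_codes"] = label
    nx.write_graphml(g, str(path), named_key_ids=True)


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """TSV edge list (source, itype, target, directed) in canonical order."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\titype\ttarget\tdirected\n")
        for e in sorted(net.edges, key=lambda e: e.key()):
            s, t = e.source, e.target
            if not e.directed and t < s:
                s, t = t, s
            fh.write(f"{s}\t{e.itype}\t{t}\t{'true' if e.directed else 'false'}\n")
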