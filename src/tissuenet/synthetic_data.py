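"""Synthetic knowledge bases, expression catalogs and pathway gene sets.

The generators emulate, at desk scale, the statistical structure the analysis
assumes: a gene universe where most genes have a protein product joined by a
directed expression edge; a scale-free-ish typed interaction topology
(hub-dominated, as literature-derived interactomes are); per-tissue
expressed-gene subsets of configurable coverage, correlated between tissues;
and pathway gene sets drawn as snowball samples so their induced networks are
non-trivially connected, the way curated process annotations are.

Defaults follow the regime of tissue-filtered pathway networks: 500 genes,
preferential attachment with 5 edges per new node (mean unit degree ~10,
matching the average-neighbor range such networks show), 5 tissues at 60%
coverage, and a 60-gene pathway.  ``hub_bias`` is the designed signal knob:
excluding the top-degree genes from one tissue makes its filtered network
measurably less central — the effect the null test is meant to detect.

All generators are pure functions of (config, seed).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np

from .kb_model import BioNode, ExpressionCatalog, Interaction, KnowledgeGraph
from .metrics import NetworkCharacteristics


@dataclass(frozen=True)
class HubBias:
    """Exclude the top ``top_degree_fraction`` of genes (by unit degree in the
    knowledge graph) from one tissue's expressed set."""

    tissue: str
    top_degree_fraction: float = 0.05


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 500
    edge_model: str = "preferential_attachment"  # or "erdos_renyi"
    attachment_edges_per_node: int = 5
    edge_probability: float = 0.02
    protein_fraction: float = 0.7
    n_tissues: int = 5
    coverage: float = 0.6
    tissue_correlation: float = 0.5
    hub_bias: Optional[HubBias] = None
    pathway_size: int = 60
    seed: int = 0

    def __post_init__(self):
        for name in ("protein_fraction", "coverage", "tissue_correlation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.edge_probability <= 1.0:
            raise ValueError("edge_probability must be in [0, 1]")
        if self.pathway_size > self.n_genes:
            raise ValueError("pathway_size exceeds n_genes")
        if self.edge_model not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown edge_model {self.edge_model!r}")
        if self.hub_bias is not None and not 0.0 <= self.hub_bias.top_degree_fraction <= 1.0:
            raise ValueError("hub_bias.top_degree_fraction must be in [0, 1]")


def _gene_id(i: int) -> str:
    return f"g{i:04d}"


def _protein_id(i: int) -> str:
    return f"p{i:04d}"


def generate_kb(config: SyntheticConfig) -> KnowledgeGraph:
    """Generate the interaction knowledge graph.

    Each of ``n_genes`` genes may carry a protein node (probability-free:
    a seeded sample of ``protein_fraction * n_genes`` genes) joined by a
    directed expression edge.  A backbone topology over gene indices (either
    Barabási–Albert preferential attachment or G(n, p)) is then lifted to
    typed edges: protein–protein ``interaction`` when both endpoints have
    proteins, gene-level ``association`` otherwise.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genes
    n_prot = int(round(config.protein_fraction * n))
    with_protein = set(rng.choice(n, size=n_prot, replace=False).tolist())

    nodes = [BioNode(_gene_id(i), "gene") for i in range(n)]
    nodes += [BioNode(_protein_id(i), "protein") for i in sorted(with_protein)]
    edges = [
        Interaction(_gene_id(i), _protein_id(i), "expression", directed=True)
        for i in sorted(with_protein)
    ]

    backbone_seed = int(rng.integers(2**31))
    if config.edge_model == "preferential_attachment":
        m = min(config.attachment_edges_per_node, max(1, n - 1))
        backbone = nx.barabasi_albert_graph(n, m, seed=backbone_seed)
    else:
        backbone = nx.gnp_random_graph(n, config.edge_probability, seed=backbone_seed)

    def unit(i: int) -> str:
        return _protein_id(i) if i in with_protein else _gene_id(i)

    for i, j in sorted(backbone.edges()):
        both_protein = i in with_protein and j in with_protein
        itype = "interaction" if both_protein else "association"
        edges.append(Interaction(unit(i), unit(j), itype, directed=False))

    return KnowledgeGraph(nodes, edges)


def _unit_degrees(kb: KnowledgeGraph) -> dict[str, int]:
    """Interaction degree of each gene's unit (its protein when it has one),
    expression edges excluded."""
    adj = kb.adjacency
    products = kb.gene_products
    out: dict[str, int] = {}
    for gid in kb.gene_universe_sorted:
        prots = products.get(gid, ())
        neighbors: set[str] = set(adj[gid]) - set(prots)
        for pid in prots:
            neighbors |= set(adj[pid]) - {gid}
        neighbors.discard(gid)
        out[gid] = len(neighbors)
    return out


def top_degree_genes(kb: KnowledgeGraph, fraction: float) -> list[str]:
    """The top ``fraction`` of genes by unit degree (ties broken by id)."""
    degrees = _unit_degrees(kb)
    k = int(np.ceil(fraction * len(degrees)))
    ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
    return [gid for gid, _ in ranked[:k]]


def generate_catalog(config: SyntheticConfig, kb: KnowledgeGraph) -> ExpressionCatalog:
    """Generate per-tissue presence calls.

    ``tissue_1`` is the base tissue: each gene is present with probability
    ``coverage``.  Every further tissue copies the base call with probability
    ``tissue_correlation`` and redraws it at ``coverage`` otherwise, so
    tissues share calls without being identical.  ``hub_bias`` (if set)
    removes the top-degree genes from its tissue *after* the draw.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = list(kb.gene_universe_sorted)
    n = len(genes)
    base = rng.random(n) < config.coverage
    calls: dict[str, set[str]] = {}
    names = [f"tissue_{k + 1}" for k in range(config.n_tissues)]
    for t, name in enumerate(names):
        if t == 0:
            mask = base
        else:
            copy = rng.random(n) < config.tissue_correlation
            fresh = rng.random(n) < config.coverage
            mask = np.where(copy, base, fresh)
        calls[name] = {g for g, m in zip(genes, mask) if m}
    if config.hub_bias is not None:
        hubs = set(top_degree_genes(kb, config.hub_bias.top_degree_fraction))
        tissue = config.hub_bias.tissue
        if tissue not in calls:
            raise ValueError(f"hub_bias tissue {tissue!r} not among generated tissues")
        calls[tissue] -= hubs
    return ExpressionCatalog(calls, tissue_names=names)


def generate_pathway(config: SyntheticConfig, kb: KnowledgeGraph) -> list[str]:
    """Sample a pathway gene set by snowball sampling.

    Starting from a random non-isolated gene, a breadth-first frontier over
    the gene-unit adjacency is consumed in seeded random order until
    ``pathway_size`` genes are collected (jumping to a fresh random gene if a
    component is exhausted).  The induced network of such a set is markedly
    more connected than that of a uniform sample of equal size.
    """
    rng = np.random.default_rng([config.seed, 2])
    genes = list(kb.gene_universe_sorted)
    target = config.pathway_size
    if target == len(genes):
        return genes

    # gene-unit adjacency: neighbor genes of a gene, through its protein(s)
    owner: dict[str, str] = {}
    for gid in genes:
        owner[gid] = gid
        for pid in kb.gene_products.get(gid, ()):
            owner[pid] = gid
    adj = kb.adjacency
    unit_adj: dict[str, set[str]] = {g: set() for g in genes}
    for node, neighbors in adj.items():
        g = owner.get(node)
        if g is None:
            continue
        for u in neighbors:
            gu = owner.get(u)
            if gu is not None and gu != g:
                unit_adj[g].add(gu)

    degrees = {g: len(ns) for g, ns in unit_adj.items()}
    nonisolated = [g for g in genes if degrees[g] > 0]
    start_pool = nonisolated if nonisolated else genes
    chosen: list[str] = []
    chosen_set: set[str] = set()
    frontier: list[str] = []

    def push(g: str) -> None:
        chosen.append(g)
        chosen_set.add(g)
        nbrs = [u for u in sorted(unit_adj[g]) if u not in chosen_set]
        rng.shuffle(nbrs)
        frontier.extend(nbrs)

    push(start_pool[int(rng.integers(len(start_pool)))])
    while len(chosen) < target:
        while frontier and frontier[-1] in chosen_set:
            frontier.pop()
        if frontier:
            push(frontier.pop())
        else:
            remaining = [g for g in genes if g not in chosen_set]
            push(remaining[int(rng.integers(len(remaining)))])
    return chosen


# ---------------------------------------------------------------------------
# worked fixture: a fixed, hand-auditable instance used across unit tests
# ---------------------------------------------------------------------------

#: Gene ids of the worked fixture's pathway (all of them).
WORKED_PATHWAY = tuple(f"g{i:02d}" for i in range(1, 13))

#: Tissue -> expressed genes of the worked fixture.
WORKED_TISSUES = {
    "T1": ("g01", "g02", "g03", "g09", "g10"),
    "T2": WORKED_PATHWAY,
    "T3": ("g04", "g05", "g06", "g07"),
}

#: Node count of the fixture network filtered by tissue T1 (5 genes + 3 proteins).
WORKED_T1_NODES = 8

#: Characteristics of the fixture's combined network, precomputed at fixture
#: creation by the exhaustive enumeration route (:mod:`tissuenet.bruteforce`).
WORKED_COMBINED_CHARACTERISTICS = NetworkCharacteristics(
    n_nodes=20,
    clustering=0.1,
    n_components=2,
    centralization=0.11695906432748537,
    n_shortest_paths=442,
    avg_neighbors=2.0,
    density=0.10526315789473684,
    heterogeneity=0.6519202405202649,
)

#: Same, for the network filtered by tissue T1.
WORKED_T1_CHARACTERISTICS = NetworkCharacteristics(
    n_nodes=8,
    clustering=0.20833333333333331,
    n_components=1,
    centralization=0.38095238095238093,
    n_shortest_paths=56,
    avg_neighbors=2.0,
    density=0.2857142857142857,
    heterogeneity=0.5590169943749475,
)


def worked_fixture() -> tuple[KnowledgeGraph, ExpressionCatalog, list[str]]:
    """A fixed 12-gene, 3-tissue instance small enough to audit by hand.

    Genes g01..g12; g01..g08 carry proteins p01..p08.  The protein layer has
    a triangle p01-p02-p03 with a tail p03-p04-p05-p06 and a branch p05-p07,
    p07-p08; the gene layer has associations g09-g10, g10-g11 and a bridge
    g09-p01; g12 is isolated.  Tissue T1 keeps 8 nodes, T2 everything, T3 the
    tail.
    """
    nodes = [BioNode(f"g{i:02d}", "gene") for i in range(1, 13)]
    nodes += [BioNode(f"p{i:02d}", "protein") for i in range(1, 9)]
    edges = [
        Interaction(f"g{i:02d}", f"p{i:02d}", "expression", directed=True)
        for i in range(1, 9)
    ]
    undirected = [
        ("p01", "p02", "interaction"),
        ("p01", "p03", "interaction"),
        ("p02", "p03", "interaction"),
        ("p03", "p04", "interaction"),
        ("p04", "p05", "catalysis"),
        ("p05", "p06", "interaction"),
        ("p05", "p07", "interaction"),
        ("p07", "p08", "association"),
        ("g09", "g10", "association"),
        ("g10", "g11", "association"),
        ("g09", "p01", "association"),
    ]
    edges += [Interaction(a, b, t, directed=False) for a, b, t in undirected]
    edges.append(Interaction("p02", "p04", "regulation", directed=True))
    kb = KnowledgeGraph(nodes, edges)
    catalog = ExpressionCatalog(
        {t: set(genes) for t, genes in WORKED_TISSUES.items()},
        tissue_names=list(WORKED_TISSUES),
    )
    return kb, catalog, list(WORKED_PATHWAY)
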