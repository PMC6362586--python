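"""Data model and file I/O for the interaction knowledge graph and the
tissue-expression catalog.

The knowledge graph holds gene and protein nodes joined by typed, optionally
directed interactions.  Genes and proteins are separate objects in one id
namespace; the only link between a protein and its encoding gene is a directed
``expression`` edge (gene -> protein), never a naming convention.

The expression catalog is a map from tissue name to the set of genes with a
*present* expression call under normal conditions (Bgee-style presence/absence
calls).  Absent calls are parsed but not stored; tissue names are case-folded
and whitespace-trimmed for lookup while the original spelling is preserved
for display.
"""
from __future__ import annotations

import csv
import difflib
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

NODE_KINDS = ("gene", "protein")
INTERACTION_TYPES = (
    "expression",
    "regulation",
    "interaction",
    "association",
    "catalysis",
    "other",
)

INTERACTIONS_COLUMNS = (
    "source_id",
    "source_kind",
    "itype",
    "target_id",
    "target_kind",
    "directed",
)
EXPRESSION_COLUMNS = ("gene_id", "tissue_name", "call")


class FormatError(ValueError):
    """A file is structurally malformed (e.g. a required column is missing)."""


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class TissueLookupError(KeyError):
    """An undeclared tissue was requested; carries near-match suggestions."""

    def __init__(self, tissue: str, suggestions: Sequence[str]):
        hint = f"; did you mean: {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(f"unknown tissue {tissue!r}{hint}")
        self.tissue = tissue
        self.suggestions = list(suggestions)


class PatternError(ValueError):
    """A tissue wildcard pattern is malformed ('*' allowed only at the end)."""


@dataclass(frozen=True)
class BioNode:
    """A gene or protein vertex of the knowledge graph."""

    id: str
    kind: str  # "gene" | "protein"
    symbol: str = ""

    def __post_init__(self):
        if self.kind not in NODE_KINDS:
            raise ValueError(f"unknown node kind {self.kind!r}")
        if not self.symbol:
            object.__setattr__(self, "symbol", self.id)


@dataclass(frozen=True)
class Interaction:
    """A typed edge.  Expression edges are always directed gene -> protein."""

    source: str
    target: str
    itype: str
    directed: bool = False

    def __post_init__(self):
        if self.itype not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {self.itype!r}")

    def key(self) -> tuple:
        """Canonical identity: undirected edges are endpoint-order insensitive."""
        if self.directed:
            return (self.source, self.target, self.itype, True)
        a, b = sorted((self.source, self.target))
        return (a, b, self.itype, False)


def _fold(name: str) -> str:
    return " ".join(name.split()).casefold()


class KnowledgeGraph:
    """The full typed gene/protein interaction graph plus the gene universe.

    Parameters
    ----------
    nodes : iterable of BioNode
    edges : iterable of Interaction
        Every endpoint must be a declared node.  Duplicate edges (by canonical
        key) collapse to one; self-loops are dropped.  Both events are logged.
    """

    def __init__(self, nodes: Iterable[BioNode], edges: Iterable[Interaction]):
        self.nodes: dict[str, BioNode] = {}
        for node in nodes:
            existing = self.nodes.get(node.id)
            if existing is not None and existing.kind != node.kind:
                raise ValueError(
                    f"node {node.id!r} declared with conflicting kinds "
                    f"{existing.kind!r} and {node.kind!r}"
                )
            self.nodes.setdefault(node.id, node)

        seen: dict[tuple, Interaction] = {}
        n_loops = 0
        n_dups = 0
        for edge in edges:
            for endpoint in (edge.source, edge.target):
                if endpoint not in self.nodes:
                    raise ValueError(f"edge endpoint {endpoint!r} is not a declared node")
            if edge.source == edge.target:
                n_loops += 1
                continue
            if edge.itype == "expression":
                if not (
                    edge.directed
                    and self.nodes[edge.source].kind == "gene"
                    and self.nodes[edge.target].kind == "protein"
                ):
                    raise ValueError(
                        f"expression edge {edge.source!r}->{edge.target!r} must be "
                        "directed gene->protein"
                    )
            key = edge.key()
            if key in seen:
                n_dups += 1
                continue
            seen[key] = edge
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        if n_dups:
            logger.info("collapsed %d duplicate edge(s)", n_dups)
        self.edges: tuple[Interaction, ...] = tuple(
            sorted(seen.values(), key=lambda e: e.key())
        )
        self.n_selfloops_dropped = n_loops
        self.n_duplicates_collapsed = n_dups

        self._adjacency: dict[str, frozenset[str]] | None = None
        self._universe_sorted: tuple[str, ...] | None = None
        self._gene_products: dict[str, tuple[str, ...]] | None = None

    # -- derived views -----------------------------------------------------

    @property
    def gene_universe(self) -> frozenset[str]:
        return frozenset(n.id for n in self.nodes.values() if n.kind == "gene")

    @property
    def gene_universe_sorted(self) -> tuple[str, ...]:
        if self._universe_sorted is None:
            self._universe_sorted = tuple(sorted(self.gene_universe))
        return self._universe_sorted

    @property
    def protein_ids(self) -> frozenset[str]:
        return frozenset(n.id for n in self.nodes.values() if n.kind == "protein")

    def proteins_of(self, gene_id: str) -> frozenset[str]:
        """Protein products of a gene, via expression edges."""
        return frozenset(
            e.target for e in self.edges if e.itype == "expression" and e.source == gene_id
        )

    def genes_encoding(self, protein_id: str) -> frozenset[str]:
        return frozenset(
            e.source for e in self.edges if e.itype == "expression" and e.target == protein_id
        )

    @property
    def gene_products(self) -> dict[str, tuple[str, ...]]:
        """Cached gene id -> tuple of protein product ids (via expression edges)."""
        if self._gene_products is None:
            out: dict[str, list[str]] = {}
            for e in self.edges:
                if e.itype == "expression":
                    out.setdefault(e.source, []).append(e.target)
            self._gene_products = {g: tuple(sorted(ps)) for g, ps in out.items()}
        return self._gene_products

    @property
    def adjacency(self) -> dict[str, frozenset[str]]:
        """Undirected simple-graph adjacency over all nodes (cached)."""
        if self._adjacency is None:
            adj: dict[str, set[str]] = {nid: set() for nid in self.nodes}
            for e in self.edges:
                adj[e.source].add(e.target)
                adj[e.target].add(e.source)
            self._adjacency = {k: frozenset(v) for k, v in adj.items()}
        return self._adjacency

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<KnowledgeGraph {len(self.nodes)} nodes "
            f"({len(self.gene_universe)} genes), {len(self.edges)} edges>"
        )


class ExpressionCatalog:
    """Tissue -> set of genes with a *present* expression call.

    Tissue names are matched case-insensitively after whitespace trimming;
    the original spelling is kept in :attr:`tissue_names` for display.
    """

    def __init__(
        self,
        calls: Mapping[str, Iterable[str]],
        tissue_names: Sequence[str] | None = None,
    ):
        if tissue_names is None:
            tissue_names = list(calls.keys())
        self.tissue_names: list[str] = []
        self._by_folded: dict[str, frozenset[str]] = {}
        self._display: dict[str, str] = {}
        for name in tissue_names:
            folded = _fold(name)
            if folded in self._display:
                raise ValueError(f"tissue name {name!r} duplicates {self._display[folded]!r} after case-folding")
            self.tissue_names.append(name)
            self._display[folded] = name
            self._by_folded[folded] = frozenset()
        for name, genes in calls.items():
            folded = _fold(name)
            if folded not in self._by_folded:
                raise ValueError(f"calls given for undeclared tissue {name!r}")
            self._by_folded[folded] = frozenset(genes)

    @property
    def gene_namespace(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self._by_folded.values():
            out |= genes
        return frozenset(out)

    def genes_expressed_in(self, tissue: str) -> frozenset[str]:
        """Present-call gene set for an exact (case-insensitive) tissue name."""
        folded = _fold(tissue)
        try:
            return self._by_folded[folded]
        except KeyError:
            suggestions = difflib.get_close_matches(folded, list(self._display), n=3)
            raise TissueLookupError(tissue, [self._display[s] for s in suggestions]) from None

    def match_tissues(self, pattern: str) -> list[str]:
        """Resolve a tissue name or trailing-'*' prefix pattern to display names.

        Without '*' the match is exact (0 or 1 result); with a trailing '*'
        every tissue whose folded name starts with the folded prefix is
        returned, sorted lexicographically.  '*' anywhere else is an error.
        """
        star = pattern.find("*")
        if star != -1 and star != len(pattern) - 1:
            raise PatternError(f"'*' only allowed at the end of a pattern: {pattern!r}")
        if star == -1:
            folded = _fold(pattern)
            return [self._display[folded]] if folded in self._display else []
        prefix = _fold(pattern[:-1])
        hits = [d for f, d in self._display.items() if f.startswith(prefix)]
        return sorted(hits, key=_fold)

    def tissue_gene_counts(self) -> pd.DataFrame:
        """One row per declared tissue with its number of expressed genes."""
        rows = [
            (name, len(self._by_folded[_fold(name)])) for name in self.tissue_names
        ]
        return pd.DataFrame(rows, columns=["tissue", "n_expressed_genes"])

    def count_histogram(self, n_bins: int = 20) -> pd.DataFrame:
        """Number of tissues per gene-count bin (tissues-vs-genes distribution)."""
        counts = self.tissue_gene_counts()["n_expressed_genes"]
        if counts.empty:
            return pd.DataFrame(columns=["bin_left", "bin_right", "n_tissues"])
        import numpy as np

        hist, edges = np.histogram(counts.to_numpy(), bins=n_bins)
        return pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "n_tissues": hist}
        )

    def plot_count_histogram(self, path: str | Path, n_bins: int = 20) -> None:
        """Save a bar plot of the tissues-per-gene-count distribution (how
        many tissues express a given number of genes)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        hist = self.count_histogram(n_bins=n_bins)
        fig, ax = plt.subplots(figsize=(7, 4))
        if not hist.empty:
            widths = (hist["bin_right"] - hist["bin_left"]).to_numpy()
            ax.bar(hist["bin_left"], hist["n_tissues"], width=widths, align="edge",
                   edgecolor="black", linewidth=0.5)
        ax.set_xlabel("number of expressed genes")
        ax.set_ylabel("number of tissues")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<ExpressionCatalog {len(self.tissue_names)} tissues, {len(self.gene_namespace)} genes>"


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _read_tsv_rows(
    path: str | Path,
    required: Sequence[str],
    comments: list[tuple[int, list[str]]] | None = None,
) -> tuple[list[str], list[tuple[int, dict[str, str]]]]:
    """Read a header-required TSV, skipping blank and '#'-comment lines.

    Returns the header and (line_number, row-dict) pairs.  Comment lines are
    appended to ``comments`` when a list is passed (used for ``#node``
    declarations of isolated vertices).
    """
    path = Path(path)
    header: list[str] | None = None
    rows: list[tuple[int, dict[str, str]]] = []
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, raw in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not raw or (len(raw) == 1 and not raw[0].strip()):
                continue
            if raw[0].lstrip().startswith("#"):
                if comments is not None:
                    comments.append((lineno, [c.strip() for c in raw]))
                continue
            if header is None:
                header = [c.strip() for c in raw]
                missing = [c for c in required if c not in header]
                if missing:
                    raise FormatError(
                        f"{path.name}: missing required column(s) {', '.join(missing)}"
                    )
                continue
            if len(raw) < len(header):
                raise ParseError(f"expected {len(header)} fields, got {len(raw)}", lineno)
            rows.append((lineno, dict(zip(header, (c.strip() for c in raw)))))
    if header is None:
        raise FormatError(f"{path.name}: empty file (header required)")
    return header, rows


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def load_interactions(path: str | Path) -> KnowledgeGraph:
    """Load a 6-column interaction TSV into a :class:`KnowledgeGraph`.

    Columns: source_id, source_kind, itype, target_id, target_kind, directed.
    Duplicate edges collapse, self-loops are dropped; both are logged.
    Isolated vertices are declared by ``#node <id> <kind>`` comment lines
    (the writer emits them, so graphs round-trip losslessly).
    """
    comments: list[tuple[int, list[str]]] = []
    _, rows = _read_tsv_rows(path, INTERACTIONS_COLUMNS, comments=comments)
    nodes: dict[str, BioNode] = {}
    edges: list[Interaction] = []
    for lineno, fields in comments:
        if fields[0] == "#node":
            if len(fields) < 3 or fields[2].casefold() not in NODE_KINDS:
                raise ParseError(f"malformed #node declaration {fields!r}", lineno)
            nodes.setdefault(fields[1], BioNode(fields[1], fields[2].casefold()))
    for lineno, row in rows:
        for id_col, kind_col in (("source_id", "source_kind"), ("target_id", "target_kind")):
            nid, kind = row[id_col], row[kind_col].casefold()
            if kind not in NODE_KINDS:
                raise ParseError(f"unknown node kind {row[kind_col]!r}", lineno)
            prev = nodes.get(nid)
            if prev is not None and prev.kind != kind:
                raise ParseError(
                    f"node {nid!r} redeclared as {kind!r} (was {prev.kind!r})", lineno
                )
            nodes.setdefault(nid, BioNode(nid, kind))
        itype = row["itype"].casefold()
        if itype not in INTERACTION_TYPES:
            raise ParseError(f"unknown interaction type {row['itype']!r}", lineno)
        directed_token = row["directed"].casefold()
        if directed_token in _TRUE:
            directed = True
        elif directed_token in _FALSE:
            directed = False
        else:
            raise ParseError(f"unknown directed token {row['directed']!r}", lineno)
        edges.append(Interaction(row["source_id"], row["target_id"], itype, directed))
    return KnowledgeGraph(nodes.values(), edges)


def write_interactions(kb: KnowledgeGraph, path: str | Path) -> None:
    """Write the canonicalized (sorted, deduplicated) edge set as TSV.

    Vertices with no edges are preserved as ``#node`` comment declarations.
    """
    path = Path(path)
    touched = {e.source for e in kb.edges} | {e.target for e in kb.edges}
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(INTERACTIONS_COLUMNS) + "\n")
        for nid in sorted(set(kb.nodes) - touched):
            fh.write(f"#node\t{nid}\t{kb.nodes[nid].kind}\n")
        for e in kb.edges:
            s, t = e.source, e.target
            if not e.directed and t < s:
                s, t = t, s
            fh.write(
                "\t".join(
                    (s, kb.nodes[s].kind, e.itype, t, kb.nodes[t].kind,
                     "true" if e.directed else "false")
                )
                + "\n"
            )


def write_sif(kb_or_edges, path: str | Path) -> None:
    """Export edges in SIF form (source, itype, target) for interoperability."""
    edges = kb_or_edges.edges if hasattr(kb_or_edges, "edges") else kb_or_edges
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for e in sorted(edges, key=lambda e: e.key()):
            s, t = e.source, e.target
            if not e.directed and t < s:
                s, t = t, s
            fh.write(f"{s}\t{e.itype}\t{t}\n")


def load_expression(path: str | Path) -> ExpressionCatalog:
    """Load a (gene_id, tissue_name, call) TSV into an :class:`ExpressionCatalog`.

    Only ``present`` rows populate the calls; ``absent`` rows still declare
    their tissue, so a tissue with no present genes is retained with an empty
    set.  Any other call token is a parse error.
    """
    _, rows = _read_tsv_rows(path, EXPRESSION_COLUMNS)
    order: list[str] = []
    folded_seen: set[str] = set()
    present: dict[str, set[str]] = {}
    for lineno, row in rows:
        tissue = row["tissue_name"]
        folded = _fold(tissue)
        if folded not in folded_seen:
            folded_seen.add(folded)
            order.append(tissue)
            present[tissue] = set()
        call = row["call"].casefold()
        if call == "present":
            display = next(t for t in order if _fold(t) == folded)
            present[display].add(row["gene_id"])
        elif call != "absent":
            raise ParseError(f"unknown call token {row['call']!r}", lineno)
    return ExpressionCatalog(present, tissue_names=order)


def write_expression(catalog: ExpressionCatalog, path: str | Path) -> None:
    """Write the catalog as a present-call TSV.

    Tissues with no present genes are declared via a single ``absent`` row
    (using the lexicographically first gene of the namespace, or a dummy id
    when the namespace is empty) so the round-trip preserves tissue_names.
    """
    path = Path(path)
    namespace = sorted(catalog.gene_namespace)
    anchor = namespace[0] if namespace else "none"
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EXPRESSION_COLUMNS) + "\n")
        for tissue in catalog.tissue_names:
            genes = sorted(catalog.genes_expressed_in(tissue))
            if not genes:
                fh.write(f"{anchor}\t{tissue}\tabsent\n")
                continue
            for g in genes:
                fh.write(f"{g}\t{tissue}\tpresent\n")


def load_gene_set(path: str | Path, set_name: str | None = None) -> tuple[str, list[str]]:
    """Load a gene set from a one-id-per-line text file or a GMT file.

    For GMT the first two fields of each line are name and description and the
    rest are gene ids; ``set_name`` selects a set (default: the first line).
    Returns ``(name, gene_ids)`` with input order preserved, duplicates removed.
    """
    path = Path(path)
    if path.suffix.casefold() == ".gmt":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                name = fields[0]
                if set_name is None or name == set_name:
                    return name, list(dict.fromkeys(f for f in fields[2:] if f))
        raise FormatError(f"{path.name}: gene set {set_name!r} not found")
    genes: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                genes.append(token)
    return path.stem, list(dict.fromkeys(genes))
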