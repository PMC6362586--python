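"""Orchestrate the full workflow and write the report bundle.

The pipeline loads a knowledge graph, an expression catalog and a gene set,
reconstructs the combined network and one tissue-specific network per
requested tissue, computes the eight structural characteristics of every
network, tests each tissue network against the combined one with the
pseudo-random null, builds the zero-imputed betweenness table and its Pearson
correlation matrix, identifies the top-central node of each network, and
exports the intermediary network around the union of those central nodes.

Reports are plain TSV plus a JSON manifest; the whole bundle is a pure
function of the inputs and one root seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from ._version import __version__
from .centrality import (
    build_centrality_table,
    correlation_matrix,
    read_supplementary_betweenness,
    top_central_nodes,
    zero_impute,
)
from .kb_model import load_expression, load_gene_set, load_interactions
from .metrics import characterize
from .null_test import INDICATOR_NAMES, run_null_test
from .reconstruct import filter_by_tissue, induce_network, intermediary_network, write_edge_list, write_graphml

logger = logging.getLogger(__name__)

#: Printed pairwise betweenness correlations of the six published networks
#: (combined plus five tissues), used for side-by-side comparison in
#: supplementary-reproduction mode.
PRINTED_CORRELATIONS = pd.DataFrame(
    [
        [1.000, 0.985, 0.804, 0.651, 0.398, 0.788],
        [0.985, 1.000, 0.772, 0.633, 0.401, 0.792],
        [0.804, 0.772, 1.000, 0.787, 0.483, 0.954],
        [0.651, 0.633, 0.787, 1.000, 0.659, 0.792],
        [0.398, 0.401, 0.483, 0.659, 1.000, 0.530],
        [0.788, 0.792, 0.954, 0.792, 0.530, 1.000],
    ],
    index=[
        "combined",
        "lymph node",
        "endometrium",
        "embryo",
        "retina",
        "substantia nigra",
    ],
    columns=[
        "combined",
        "lymph node",
        "endometrium",
        "embryo",
        "retina",
        "substantia nigra",
    ],
)


@dataclass(frozen=True)
class PipelineConfig:
    """Inputs, tissue list, null-test settings and convention flags."""

    kb_path: str
    expression_path: str
    gene_set_path: str
    tissues: tuple[str, ...]
    replicates: int = 1000
    seed: int = 17
    out_dir: str = "tissuenet_out"
    clustering_all_nodes: bool = False
    betweenness_scale: str = "normalized"  # or "raw"
    vertex_budget: str = "genes"  # or "nodes"
    pairs_only: bool = False
    min_links: int = 2

    def __post_init__(self):
        if not self.tissues:
            raise ValueError("tissue list must be nonempty")
        if self.betweenness_scale not in ("normalized", "raw"):
            raise ValueError(f"unknown betweenness_scale {self.betweenness_scale!r}")
        if self.vertex_budget not in ("genes", "nodes"):
            raise ValueError(f"unknown vertex_budget {self.vertex_budget!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["tissues"] = tuple(raw["tissues"])
        return cls(**raw)


@dataclass(frozen=True)
class PipelineResult:
    """In-memory view of the report bundle."""

    characteristics: pd.DataFrame
    significance: pd.DataFrame
    betweenness_table: pd.DataFrame
    correlations: pd.DataFrame
    top_central: dict[str, str]
    null_results: dict[str, dict]
    out_dir: Path


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Outputs: characteristics.tsv (eight metric rows x one column per network,
    plus a parallel matrix of significance markers), betweenness.tsv,
    correlations.tsv, top_central.tsv, intermediary.graphml / .tsv,
    null_results.json and manifest.json.  Any stage error aborts with the
    stage name and removes partial outputs.
    """
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        kb = load_interactions(config.kb_path)
        catalog = load_expression(config.expression_path)
        set_name, genes = load_gene_set(config.gene_set_path)

        stage = "resolve-tissues"
        tissues: list[str] = []
        for pattern in config.tissues:
            matches = catalog.match_tissues(pattern)
            if not matches:
                raise ValueError(f"tissue pattern {pattern!r} matched nothing")
            for m in matches:
                if m not in tissues:
                    tissues.append(m)

        stage = "reconstruct"
        combined = induce_network(kb, genes, "combined")
        networks: list[tuple[str, object]] = [("combined", combined)]
        for tissue in tissues:
            networks.append((tissue, filter_by_tissue(combined, catalog, tissue)))

        stage = "characterize"
        opts = dict(
            all_nodes_clustering=config.clustering_all_nodes,
            pairs_only=config.pairs_only,
        )
        chars = {name: characterize(net, **opts) for name, net in networks}
        characteristics = pd.DataFrame(
            {name: pd.Series(c.as_dict()) for name, c in chars.items()}
        ).reindex(list(chars[next(iter(chars))].FIELD_ORDER))

        stage = "null-test"
        null_results: dict[str, dict] = {}
        significance = pd.DataFrame(
            "", index=characteristics.index, columns=characteristics.columns
        )
        for j, tissue in enumerate(tissues):
            net = dict(networks)[tissue]
            if net.n_nodes == 0:
                logger.warning("skipping null test for empty network %r", tissue)
                continue
            result = run_null_test(
                kb,
                combined,
                net,
                replicates=config.replicates,
                seed=int(config.seed) * 1000 + j,
                vertex_budget=config.vertex_budget,
                all_nodes_clustering=config.clustering_all_nodes,
                pairs_only=config.pairs_only,
            )
            null_results[tissue] = result.to_dict()
            for indicator in INDICATOR_NAMES:
                if result.significant[indicator]:
                    significance.at[indicator, tissue] = "*"

        stage = "centrality"
        nonempty = [(n, net) for n, net in networks if net.n_nodes > 0]
        table = build_centrality_table(
            nonempty, normalized=config.betweenness_scale == "normalized"
        )
        corr = correlation_matrix(table)
        top = {name: top_central_nodes(net)[0] for name, net in nonempty}

        stage = "intermediary"
        central_union = sorted(set(top.values()))
        inter = intermediary_network(kb, central_union, min_links=min(config.min_links, max(1, len(central_union))))

        stage = "write"
        _write_tsv(characteristics, out_dir / "characteristics.tsv", index_label="characteristic")
        _write_tsv(significance, out_dir / "significance.tsv", index_label="characteristic")
        _write_tsv(table, out_dir / "betweenness.tsv")
        _write_tsv(corr, out_dir / "correlations.tsv", index_label="network")
        pd.DataFrame(
            sorted(top.items()), columns=["network", "top_central_node"]
        ).to_csv(out_dir / "top_central.tsv", sep="\t", index=False, lineterminator="\n")
        write_graphml(inter, out_dir / "intermediary.graphml")
        write_edge_list(inter, out_dir / "intermediary.tsv")
        for name, net in networks:
            write_graphml(net, out_dir / f"network_{name.replace(' ', '_')}.graphml")
        with open(out_dir / "null_results.json", "w", encoding="utf-8") as fh:
            json.dump(null_results, fh, indent=2, sort_keys=True)
        manifest = {
            "seed": config.seed,
            "replicates": config.replicates,
            "gene_set": set_name,
            "tissues": tissues,
            "flags": {
                "clustering_all_nodes": config.clustering_all_nodes,
                "betweenness_scale": config.betweenness_scale,
                "vertex_budget": config.vertex_budget,
                "pairs_only": config.pairs_only,
                "min_links": config.min_links,
            },
            "inputs": {
                "kb": _sha256(config.kb_path),
                "expression": _sha256(config.expression_path),
                "gene_set": _sha256(config.gene_set_path),
            },
            "network_sizes": {name: net.n_nodes for name, net in networks},
            "version": __version__,
        }
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        if created:
            shutil.rmtree(out_dir, ignore_errors=True)
        else:
            for f in out_dir.iterdir():
                if f.is_file():
                    f.unlink()
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        characteristics=characteristics,
        significance=significance,
        betweenness_table=table,
        correlations=corr,
        top_central=top,
        null_results=null_results,
        out_dir=out_dir,
    )


def reproduce_supplementary(
    table_path: str | Path,
    printed: pd.DataFrame | None = None,
    node_kinds: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Recompute the cross-network betweenness correlation matrix from a
    per-vertex betweenness spreadsheet and compare it with printed values.

    The spreadsheet holds one id column plus one betweenness column per
    network; vertices absent from a network (blank cells) are zero-imputed,
    then pairwise Pearson correlations are taken over all rows.  Per-column
    positive rescaling cannot change the result, so raw-vs-normalized
    betweenness is immaterial.

    Returns ``{"computed": matrix, "comparison": long-form side-by-side}``
    and, when ``node_kinds`` distinguishes genes from proteins,
    ``"computed_genes_only"``.
    """
    raw = read_supplementary_betweenness(table_path)
    table = zero_impute(raw)
    computed = correlation_matrix(table)
    if printed is None:
        printed = PRINTED_CORRELATIONS
    rows = []
    for a in computed.index:
        for b in computed.columns:
            row = {"network_a": a, "network_b": b, "computed": computed.at[a, b]}
            if a in printed.index and b in printed.columns:
                row["printed"] = printed.at[a, b]
                row["abs_diff"] = abs(row["computed"] - row["printed"])
            rows.append(row)
    out = {"computed": computed, "comparison": pd.DataFrame(rows)}
    if node_kinds is not None:
        gene_rows = [i for i in table.index if node_kinds.get(i) == "gene"]
        if len(gene_rows) >= 2:
            out["computed_genes_only"] = correlation_matrix(table.loc[gene_rows])
    return out
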