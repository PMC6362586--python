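"""Cross-network betweenness tables with zero imputation and their pairwise
Pearson correlations.

A vertex absent from a network gets betweenness 0 in that network's column —
the comparison runs over the union of vertices, not the intersection.  Note
that per-column positive rescaling (raw vs normalized betweenness) leaves
Pearson correlations unchanged, so the correlation matrix does not depend on
the betweenness scale.
"""
from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import betweenness, project
from .reconstruct import GeneNetwork

logger = logging.getLogger(__name__)


def build_centrality_table(
    nets: Sequence[tuple[str, GeneNetwork]] | Mapping[str, GeneNetwork],
    normalized: bool = True,
) -> pd.DataFrame:
    """Betweenness of every vertex in every network, zero-imputed.

    Rows are the lexicographically sorted union of node ids across networks;
    columns are network names (input order).  A vertex absent from a network
    contributes 0 in that column.
    """
    if isinstance(nets, Mapping):
        items = list(nets.items())
    else:
        items = list(nets)
    if len(items) < 2:
        raise ValueError("need at least two networks")
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("duplicate network names")
    union: set[str] = set()
    for _, net in items:
        union |= set(net.nodes)
    index = sorted(union)
    table = pd.DataFrame(0.0, index=index, columns=names)
    for name, net in items:
        bc = betweenness(project(net), normalized=normalized)
        for nid, value in bc.items():
            table.at[nid, name] = value
    table.index.name = "node"
    return table


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of the table's columns (zeros included).

    Zero-variance columns yield NaN entries off-diagonal (flagged with a
    warning, never silently zeroed); the diagonal is exactly 1.
    """
    if len(table) < 2:
        raise ValueError("need at least two rows to correlate")
    values = table.to_numpy(dtype=float)
    stds = values.std(axis=0)
    flat = [c for c, s in zip(table.columns, stds) if s == 0.0]
    if flat:
        warnings.warn(
            f"zero-variance column(s), correlations undefined: {', '.join(map(str, flat))}",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=table.columns, columns=table.columns)


def top_central_nodes(net: GeneNetwork, k: int = 1) -> list[str]:
    """The k vertices of maximal betweenness, ties broken lexicographically.

    Ties at the cut are logged (a unique 'most central node' claim presumes a
    unique maximum); k beyond the node count returns a truncated list with a
    warning.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    if k > net.n_nodes:
        logger.warning("k=%d exceeds node count %d; truncating", k, net.n_nodes)
        k = net.n_nodes
    bc = betweenness(project(net))
    ranked = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > k and ranked[k - 1][1] == ranked[k][1]:
        logger.info(
            "betweenness tie at rank %d in %r (value %.6g)", k, net.name, ranked[k][1]
        )
    return [nid for nid, _ in ranked[:k]]


def read_supplementary_betweenness(
    path: str | Path, sheet: int | str = 0
) -> pd.DataFrame:
    """Read a per-vertex betweenness spreadsheet (one id column + one column
    per network).

    Accepts an Excel workbook (first sheet by default) or a TSV with the same
    layout.  Missing cells mean the vertex is absent from that network and are
    zero-imputed downstream.
    """
    path = Path(path)
    if path.suffix.casefold() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(
            f"{path.name}: expected an id column plus >=2 network columns, "
            f"got {df.shape[1]} column(s)"
        )
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "node"
    for c in df.columns:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def zero_impute(table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing betweenness values (vertex absent from a network) by 0."""
    return table.fillna(0.0)
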