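"""Significance of structural differences via pseudo-random induced networks.

The null model resamples the knowledge graph: vertices are drawn uniformly
without replacement from the full gene universe and the network among them is
reconstructed with the same rule as the real networks (seed genes plus their
proteins, induced edges).  For a pair of real networks A and B, an ensemble of
index-paired pseudo-random networks size-matched to A and to B yields a null
distribution of the seven difference indicators (node count excluded);
significance of the observed difference is declared when it falls strictly
below the 5% or strictly above the 95% empirical quantile of that
distribution.

Randomness: one root seed; replicate i draws its two networks from
independent streams ``default_rng([seed, i, 0])`` and ``default_rng([seed,
i, 1])`` — a counter scheme, so replicates are reproducible regardless of
evaluation order.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kb_model import KnowledgeGraph
from .metrics import NetworkCharacteristics, characterize, induced_simple_graph
from .reconstruct import GeneNetwork, induce_network

#: The seven difference indicators, in fixed order (node count is excluded:
#: pseudo-random networks are size-matched by construction).
INDICATOR_NAMES = (
    "clustering",
    "n_components",
    "centralization",
    "n_shortest_paths",
    "avg_neighbors",
    "density",
    "heterogeneity",
)


@dataclass(frozen=True)
class DifferenceIndicators:
    """Signed differences (network A - network B) of the seven indicators."""

    clustering: float
    n_components: float
    centralization: float
    n_shortest_paths: float
    avg_neighbors: float
    density: float
    heterogeneity: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in INDICATOR_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in INDICATOR_NAMES}

    def __neg__(self) -> "DifferenceIndicators":
        return DifferenceIndicators(*(-getattr(self, k) for k in INDICATOR_NAMES))


def difference_indicators(
    a: NetworkCharacteristics, b: NetworkCharacteristics
) -> DifferenceIndicators:
    """Component-wise a - b on the seven indicator fields."""
    return DifferenceIndicators(
        *(float(getattr(a, k)) - float(getattr(b, k)) for k in INDICATOR_NAMES)
    )


def empirical_quantile(sample: Sequence[float], q: float) -> float:
    """Order-statistic quantile with linear interpolation between closest ranks.

    The interpolation is the standard linear rule on rank positions
    (numpy's ``method='linear'``): for a sorted sample x_1..x_n the quantile
    sits at position 1 + (n-1)q.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.size == 0:
        raise ValueError("empty sample")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    return float(np.quantile(sample, q, method="linear"))


def sample_pseudorandom_network(
    kb: KnowledgeGraph, n: int, rng: np.random.Generator, name: str = "pseudorandom"
) -> GeneNetwork:
    """A network induced by n genes sampled uniformly without replacement
    from the gene universe — one draw of the null model."""
    universe = kb.gene_universe_sorted
    if not 1 <= n <= len(universe):
        raise ValueError(f"sample size {n} outside 1..{len(universe)}")
    idx = rng.choice(len(universe), size=n, replace=False)
    genes = {universe[i] for i in idx}
    return induce_network(kb, genes, name)


def _sample_genes(kb: KnowledgeGraph, n: int, rng: np.random.Generator) -> set[str]:
    universe = kb.gene_universe_sorted
    idx = rng.choice(len(universe), size=n, replace=False)
    return {universe[i] for i in idx}


@dataclass(frozen=True)
class NullTestResult:
    """Observed indicator differences against their pseudo-random null.

    ``significant_low`` / ``significant_high`` flag observed values strictly
    below q05 / strictly above q95 (ties at the quantile are non-significant).
    The two tails at 5% each imply a 10% two-sided level; ``significant``
    (either tail) corresponds to the conventional single-star report.
    """

    observed: DifferenceIndicators
    null_samples: np.ndarray  # (replicates, 7)
    q05: dict[str, float]
    q95: dict[str, float]
    significant_low: dict[str, bool]
    significant_high: dict[str, bool]
    replicates: int
    seed: int

    @property
    def significant(self) -> dict[str, bool]:
        """Either-tail flag per indicator (the p < 0.05-per-tail convention)."""
        return {
            k: self.significant_low[k] or self.significant_high[k]
            for k in INDICATOR_NAMES
        }

    def to_dict(self, keep_null: bool = False) -> dict:
        out = {
            "observed": self.observed.as_dict(),
            "q05": self.q05,
            "q95": self.q95,
            "significant_low": self.significant_low,
            "significant_high": self.significant_high,
            "significant": self.significant,
            "replicates": self.replicates,
            "seed": self.seed,
        }
        if keep_null:
            out["null_samples"] = self.null_samples.tolist()
        return out


def run_null_test(
    kb: KnowledgeGraph,
    net_a: GeneNetwork,
    net_b: GeneNetwork,
    replicates: int = 1000,
    seed: int = 0,
    vertex_budget: str = "genes",
    all_nodes_clustering: bool = False,
    pairs_only: bool = False,
) -> NullTestResult:
    """Test the observed A-vs-B indicator differences against the null.

    For each replicate a pseudo-random network size-matched to A and one
    size-matched to B are drawn (index-paired, forming a single ensemble of
    paired differences shared by all seven indicators).  ``vertex_budget``
    controls the size match: ``"genes"`` samples as many genes as the real
    network contains (the universe holds genes, so gene count is the natural
    budget); ``"nodes"`` samples as many genes as the real network has total
    vertices.

    Fully reproducible from ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if net_a.n_nodes == 0 or net_b.n_nodes == 0:
        raise ValueError("both networks must be nonempty")
    if vertex_budget == "genes":
        n_a, n_b = len(net_a.gene_ids), len(net_b.gene_ids)
    elif vertex_budget == "nodes":
        n_a, n_b = net_a.n_nodes, net_b.n_nodes
    else:
        raise ValueError(f"unknown vertex_budget {vertex_budget!r}")
    n_universe = len(kb.gene_universe_sorted)
    if max(n_a, n_b) > n_universe:
        raise ValueError(
            f"size budget {max(n_a, n_b)} exceeds the {n_universe}-gene universe"
        )

    opts = dict(all_nodes_clustering=all_nodes_clustering, pairs_only=pairs_only)
    observed = difference_indicators(
        characterize(net_a, **opts), characterize(net_b, **opts)
    )

    # a budget equal to the whole universe always draws the same network;
    # characterize it once instead of per replicate
    full_char = (
        characterize(induced_simple_graph(kb, kb.gene_universe_sorted), **opts)
        if n_universe in (n_a, n_b)
        else None
    )

    def _null_char(n: int, stream: list[int]):
        if n == n_universe:
            return full_char
        genes = _sample_genes(kb, n, np.random.default_rng(stream))
        return characterize(induced_simple_graph(kb, genes), **opts)

    null = np.empty((replicates, len(INDICATOR_NAMES)), dtype=float)
    for i in range(replicates):
        diff = difference_indicators(
            _null_char(n_a, [seed, i, 0]), _null_char(n_b, [seed, i, 1])
        )
        null[i] = diff.as_array()

    q05 = {k: empirical_quantile(null[:, j], 0.05) for j, k in enumerate(INDICATOR_NAMES)}
    q95 = {k: empirical_quantile(null[:, j], 0.95) for j, k in enumerate(INDICATOR_NAMES)}
    obs = observed.as_dict()
    low = {k: bool(obs[k] < q05[k]) for k in INDICATOR_NAMES}
    high = {k: bool(obs[k] > q95[k]) for k in INDICATOR_NAMES}
    return NullTestResult(
        observed=observed,
        null_samples=null,
        q05=q05,
        q95=q95,
        significant_low=low,
        significant_high=high,
        replicates=replicates,
        seed=seed,
    )
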