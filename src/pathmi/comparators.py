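"""Comparison methods: ARACNe-style pruning and the MI minimum spanning tree.

Both infer a network first; linear paths are then extracted from the
inferred network by a unit-weight shortest-path (fewest hops) search,
contrasting with the direct shortest-path inference of probable pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from heapq import heappop, heappush

import numpy as np

from .dpi import WeightedGraph, triplet_support
from .io import ExpressionMatrix, Path, RegulatoryNetwork, SymmetricGeneMatrix
from .mi import MIEstimatorConfig, estimate_mi_pair
from .paths import dijkstra

__all__ = [
    "AracneConfig",
    "permutation_threshold",
    "aracne_network",
    "mst_network",
    "extract_path",
]

_PAIRS_PER_PERMUTATION = 5


@dataclass(frozen=True)
class AracneConfig:
    """ARACNe settings: permutation-test significance and DPI tolerance.

    ``dpi_tolerance`` is a relative margin: edge (A,B) is pruned only when
    I(A,B) < (1 - tolerance) * min(I(A,C), I(B,C)) for some C.  Path
    extraction works best with a stringent tolerance and a permissive
    significance level, hence the defaults.
    """

    n_permutations: int = 100
    significance_alpha: float = 0.30
    dpi_tolerance: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not 0.0 < self.significance_alpha <= 1.0:
            raise ValueError("significance_alpha must be in (0, 1]")
        if not 0.0 <= self.dpi_tolerance < 1.0:
            raise ValueError("dpi_tolerance must be in [0, 1)")


def permutation_threshold(expr: ExpressionMatrix, config: AracneConfig,
                          mi_config: MIEstimatorConfig | None = None) -> float:
    """(1 - alpha) quantile of the null MI distribution.

    The null is built by permuting each gene's sample order independently
    (destroying all dependence) and estimating MI for a handful of random
    gene pairs per permutation round.
    """
    if config.n_permutations < 10:
        raise ValueError("need at least 10 permutation rounds for a stable null")
    mi_config = mi_config or MIEstimatorConfig()
    rng = np.random.default_rng(config.seed)
    n_genes, n_samples = expr.n_genes, expr.n_samples
    null: list[float] = []
    n_pairs = min(_PAIRS_PER_PERMUTATION, n_genes * (n_genes - 1) // 2)
    for _ in range(config.n_permutations):
        permuted = np.stack([expr.values[g][rng.permutation(n_samples)]
                             for g in range(n_genes)])
        for _ in range(n_pairs):
            i, j = rng.choice(n_genes, size=2, replace=False)
            null.append(estimate_mi_pair(permuted[i], permuted[j], mi_config))
    return float(np.quantile(null, 1.0 - config.significance_alpha))


def aracne_network(mi: SymmetricGeneMatrix, threshold: float,
                   tolerance: float = 0.0) -> RegulatoryNetwork:
    """MI-threshold plus DPI pruning with a relative tolerance margin.

    Edge (A,B) is kept iff I(A,B) > 0, I(A,B) >= threshold, and no third
    gene C satisfies I(A,B) < (1 - tolerance) * min(I(A,C), I(B,C)).
    At tolerance 0 this reduces to the strict DPI classification
    intersected with the significance filter.
    """
    if not 0.0 <= tolerance < 1.0:
        raise ValueError("tolerance must be in [0, 1)")
    values = mi.values
    support = triplet_support(mi)
    keep = (values > 0) & (values >= threshold) & (values >= (1.0 - tolerance) * support)
    np.fill_diagonal(keep, False)
    genes = mi.gene_ids
    edges = {(genes[i], genes[j])
             for i in range(len(genes)) for j in range(i + 1, len(genes)) if keep[i, j]}
    return RegulatoryNetwork(genes, frozenset(edges), directed=False)


def _prim_forest(genes: tuple[str, ...], weight: np.ndarray) -> set[tuple[str, str]]:
    """Prim's algorithm, restarted per component at the smallest unvisited
    label; equal-weight frontier ties broken by (new node, tree node) label."""
    n = len(genes)
    order = sorted(range(n), key=lambda i: genes[i])
    visited: set[int] = set()
    edges: set[tuple[str, str]] = set()
    for start in order:
        if start in visited:
            continue
        visited.add(start)
        frontier: list[tuple[float, str, str, int, int]] = []
        for j in range(n):
            if j != start and math.isfinite(weight[start, j]):
                heappush(frontier, (weight[start, j], genes[j], genes[start], j, start))
        while frontier:
            w, _, _, j, i = heappop(frontier)
            if j in visited:
                continue
            visited.add(j)
            edges.add(tuple(sorted((genes[i], genes[j]))))  # type: ignore[arg-type]
            for k in range(n):
                if k not in visited and math.isfinite(weight[j, k]):
                    heappush(frontier, (weight[j, k], genes[k], genes[j], k, j))
    return edges


def mst_network(mi: SymmetricGeneMatrix, transform: str = "subtract-from-one") -> RegulatoryNetwork:
    """Minimum spanning tree on transformed MI (Prim's algorithm).

    Transforms (both strictly decreasing in MI, so they induce the same
    edge ordering wherever all MI values are positive):

    - ``subtract-from-one``: weight = 1 - I / I_max
    - ``negative-log``: weight = -log(I / I_max); zero-MI edges excluded
    """
    if transform not in ("subtract-from-one", "negative-log"):
        raise ValueError(f"unknown transform {transform!r}")
    if mi.n_genes < 2:
        raise ValueError("need at least 2 genes")
    values = mi.values.copy()
    np.fill_diagonal(values, np.nan)
    off = ~np.isnan(values)
    i_max = np.max(values[off]) if np.any(off) else 0.0
    if not i_max > 0:
        raise ValueError("all-zero MI matrix: no spanning criterion")
    if transform == "subtract-from-one":
        weight = 1.0 - values / i_max
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            weight = np.where(values > 0, -np.log(values / i_max), np.inf)
    weight = np.where(np.isnan(weight), np.inf, weight)
    edges = _prim_forest(mi.gene_ids, weight)
    return RegulatoryNetwork(mi.gene_ids, frozenset(edges), directed=False)


def extract_path(network: RegulatoryNetwork, root: str, target: str) -> Path | None:
    """Fewest-hop path through an inferred network (unit edge weights).

    Returns None when the target is unreachable.  Tie-breaking matches the
    probabilistic search: lexicographically smallest predecessor wins.
    """
    for node in (root, target):
        if node not in network.gene_ids:
            raise KeyError(f"unknown gene {node!r}")
    und = network.undirected_view()
    graph = WeightedGraph.from_unit_edges(und.gene_ids, und.edges)
    return dijkstra(graph, root).path_to(target)
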