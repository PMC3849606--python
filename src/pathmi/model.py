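"""Model-style front end: fit an inference method to an expression matrix.

``DirectPathModel`` bundles the full probabilistic pipeline — bootstrap MI
estimation, DPI classification, edge probabilities, negative-log weights —
behind a ``fit()`` that returns a ``DirectPathResults`` carrying the edge
probability matrix and path queries.  ``AracneModel`` and ``MSTModel`` wrap
the comparator methods the same way, returning a ``NetworkResults`` whose
paths come from unit-weight extraction on the inferred network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import comparators, dpi, mi, paths
from .io import ExpressionMatrix, Path, RegulatoryNetwork, SymmetricGeneMatrix

__all__ = ["DirectPathModel", "DirectPathResults", "AracneModel", "MSTModel", "NetworkResults"]


class DirectPathModel:
    """Shortest-path inference of probable regulatory pathways.

    Parameters
    ----------
    expr : ExpressionMatrix
        Genes-by-samples expression data.
    mi_config : MIEstimatorConfig, optional
        Mutual-information estimator settings.
    n_boot : int
        Bootstrap rounds used to estimate each edge's probability of
        directness.
    smoothing : {'laplace', 'none'}
        Probability smoothing; laplace keeps probabilities in (0, 1).
    probability_floor : float, optional
        Safety clamp applied before the negative-log transform; defaults
        to 1 / (10 * n_boot).
    """

    def __init__(self, expr: ExpressionMatrix,
                 mi_config: mi.MIEstimatorConfig | None = None,
                 n_boot: int = 100,
                 smoothing: str = "laplace",
                 probability_floor: float | None = None) -> None:
        self.expr = expr
        self.mi_config = mi_config or mi.MIEstimatorConfig()
        self.n_boot = n_boot
        self.smoothing = smoothing
        self.probability_floor = probability_floor

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "DirectPathModel":
        return cls(ExpressionMatrix.from_dataframe(df), **kwargs)

    def fit(self, seed: int = 0) -> "DirectPathResults":
        boot = mi.bootstrap_mi_matrices(self.expr, self.mi_config, self.n_boot, seed)
        directness = dpi.edge_probabilities(boot, self.smoothing)
        return DirectPathResults(model=self, directness=directness, seed=seed)


@dataclass
class DirectPathResults:
    """Fitted edge probabilities of directness and derived path queries."""

    model: DirectPathModel
    directness: dpi.DirectnessResult
    seed: int

    @property
    def edge_probability(self) -> SymmetricGeneMatrix:
        return self.directness.probability

    def to_weighted_graph(self) -> dpi.WeightedGraph:
        return dpi.to_weighted_graph(self.directness, self.model.probability_floor)

    def most_probable_path(self, root: str, target: str,
                           max_edges: int | None = None) -> Path:
        return paths.most_probable_path(self.directness, root, target,
                                        self.model.probability_floor, max_edges)

    def rank_paths(self, pairs: list[tuple[str, str]],
                   max_edges: int | None = None) -> list[Path]:
        return paths.rank_paths(self.directness, pairs,
                                self.model.probability_floor, max_edges)

    def summary(self, top: int = 10) -> str:
        genes = self.directness.gene_ids
        p = self.directness.probability.values
        iu = np.triu_indices(len(genes), k=1)
        order = np.argsort(-p[iu])
        lines = [
            "Direct-path inference results",
            "=" * 45,
            f"genes:            {len(genes)}",
            f"samples:          {self.model.expr.n_samples}",
            f"bootstraps:       {self.directness.n_boot}",
            f"MI estimator:     {self.model.mi_config.estimator} "
            f"(bins={self.model.mi_config.n_bins})",
            f"smoothing:        {self.directness.smoothing}",
            f"seed:             {self.seed}",
            "",
            f"top {min(top, len(order))} edges by probability of directness:",
            f"{'edge':<20}{'P(direct)':>12}{'-log P':>10}",
        ]
        for k in order[:top]:
            i, j = iu[0][k], iu[1][k]
            prob = p[i, j]
            lines.append(f"{genes[i]+'--'+genes[j]:<20}{prob:>12.4f}{-math.log(prob):>10.4f}")
        return "\n".join(lines)


@dataclass
class NetworkResults:
    """An inferred network plus unit-weight path extraction."""

    method: str
    network: RegulatoryNetwork
    params: dict = field(default_factory=dict)

    def extract_path(self, root: str, target: str) -> Path | None:
        return comparators.extract_path(self.network, root, target)

    def summary(self) -> str:
        lines = [
            f"{self.method} network inference results",
            "=" * 45,
            f"genes:   {len(self.network.gene_ids)}",
            f"edges:   {self.network.n_edges}",
        ]
        for k, v in self.params.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines)


def _aggregate_or_plain_mi(expr: ExpressionMatrix, mi_config, boot_aggregate,
                           n_boot, seed) -> SymmetricGeneMatrix:
    if boot_aggregate is None or boot_aggregate == "none":
        return mi.estimate_mi_matrix(expr, mi_config)
    boot = mi.bootstrap_mi_matrices(expr, mi_config, n_boot, seed)
    return mi.aggregate_bootstrap_mi(boot, boot_aggregate)


class AracneModel:
    """ARACNe-style inference: permutation-test MI threshold + DPI pruning.

    ``boot_aggregate`` ('mean' or 'median') replaces the single-shot MI
    matrix with a bootstrap aggregate, trading some sensitivity for
    robustness to outliers.
    """

    def __init__(self, expr: ExpressionMatrix,
                 config: comparators.AracneConfig | None = None,
                 mi_config: mi.MIEstimatorConfig | None = None,
                 boot_aggregate: str | None = None,
                 n_boot: int = 100) -> None:
        self.expr = expr
        self.config = config or comparators.AracneConfig()
        self.mi_config = mi_config or mi.MIEstimatorConfig()
        self.boot_aggregate = boot_aggregate
        self.n_boot = n_boot

    def fit(self) -> NetworkResults:
        threshold = comparators.permutation_threshold(self.expr, self.config, self.mi_config)
        mi_mat = _aggregate_or_plain_mi(self.expr, self.mi_config, self.boot_aggregate,
                                        self.n_boot, self.config.seed)
        net = comparators.aracne_network(mi_mat, threshold, self.config.dpi_tolerance)
        return NetworkResults("ARACNe", net, {
            "threshold": threshold,
            "alpha": self.config.significance_alpha,
            "tolerance": self.config.dpi_tolerance,
            "boot_aggregate": self.boot_aggregate or "none",
        })


class MSTModel:
    """Minimum-spanning-tree inference on transformed MI (Prim's algorithm)."""

    def __init__(self, expr: ExpressionMatrix,
                 mi_config: mi.MIEstimatorConfig | None = None,
                 transform: str = "subtract-from-one",
                 boot_aggregate: str | None = None,
                 n_boot: int = 100,
                 seed: int = 0) -> None:
        self.expr = expr
        self.mi_config = mi_config or mi.MIEstimatorConfig()
        self.transform = transform
        self.boot_aggregate = boot_aggregate
        self.n_boot = n_boot
        self.seed = seed

    def fit(self) -> NetworkResults:
        mi_mat = _aggregate_or_plain_mi(self.expr, self.mi_config, self.boot_aggregate,
                                        self.n_boot, self.seed)
        net = comparators.mst_network(mi_mat, self.transform)
        return NetworkResults("MST", net, {
            "transform": self.transform,
            "boot_aggregate": self.boot_aggregate or "none",
        })
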