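"""Edge directness via the data processing inequality (DPI).

For a trio of genes A, B, C where A influences C only through B, the DPI
gives I(A;C) <= min(I(A;B), I(B;C)); in a biological setting the inequality
can be taken to be strict.  An edge (A,B) is therefore classified *direct*
iff it is never strictly the least edge in any triplet comparison with a
third gene C.  Running the classification on each bootstrap MI matrix and
counting the rounds in which an edge survives yields its probability of
directness; the negative log of that probability is the shortest-path edge
weight, so minimising total weight maximises the joint product of edge
probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import SymmetricGeneMatrix

__all__ = [
    "DirectnessResult",
    "WeightedGraph",
    "dpi_classify",
    "triplet_support",
    "edge_probabilities",
    "to_weighted_graph",
]


def triplet_support(mi: SymmetricGeneMatrix | np.ndarray) -> np.ndarray:
    """For each pair (A,B), max over third genes C of min(I(A,C), I(B,C)).

    An edge is pruned by the DPI exactly when its MI falls strictly below
    this value.  The diagonal of the result is -inf (no valid triplet).
    """
    values = mi.values if isinstance(mi, SymmetricGeneMatrix) else np.asarray(mi, dtype=float)
    m = values.copy()
    np.fill_diagonal(m, -np.inf)  # C == A or C == B never competes
    # best[i, j] = max_c min(m[i, c], m[j, c]); n^3 broadcast is fine at GRN scale
    best = np.min(np.stack([np.broadcast_to(m[:, None, :], (len(m),) * 3),
                            np.broadcast_to(m[None, :, :], (len(m),) * 3)]), axis=0).max(axis=2)
    np.fill_diagonal(best, -np.inf)
    return best


def dpi_classify(mi: SymmetricGeneMatrix | np.ndarray) -> np.ndarray:
    """Boolean symmetric matrix: True where the edge is classified direct.

    Edge (A,B) is indirect iff some third gene C gives
    I(A,B) < min(I(A,C), I(B,C)); ties leave the edge direct (the
    inequality must be strict to prune).  The diagonal is False.
    """
    values = mi.values if isinstance(mi, SymmetricGeneMatrix) else np.asarray(mi, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    off = values.copy()
    np.fill_diagonal(off, -np.inf)
    direct = off >= triplet_support(values)
    np.fill_diagonal(direct, False)
    return direct


@dataclass(frozen=True)
class DirectnessResult:
    """Per-edge probability of directness accumulated over bootstraps."""

    probability: SymmetricGeneMatrix
    n_boot: int
    smoothing: str

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.probability.gene_ids


def edge_probabilities(boot_mi: list[SymmetricGeneMatrix],
                       smoothing: str = "laplace") -> DirectnessResult:
    """Probability of directness = fraction of bootstrap rounds an edge
    survives every DPI triplet comparison.

    Laplace smoothing maps a count c to (c + 1) / (n_boot + 2), keeping all
    probabilities strictly inside (0, 1) so the negative-log weights stay
    finite; ``smoothing='none'`` reports the raw proportion.
    """
    if not boot_mi:
        raise ValueError("need at least one bootstrap MI matrix")
    if smoothing not in ("laplace", "none"):
        raise ValueError(f"unknown smoothing {smoothing!r}")
    genes = boot_mi[0].gene_ids
    for m in boot_mi[1:]:
        if m.gene_ids != genes:
            raise ValueError("all bootstrap matrices must share the same gene set")
    counts = np.zeros((len(genes), len(genes)))
    for m in boot_mi:
        counts += dpi_classify(m)
    n_boot = len(boot_mi)
    if smoothing == "laplace":
        prob = (counts + 1.0) / (n_boot + 2.0)
    else:
        prob = counts / n_boot
    return DirectnessResult(SymmetricGeneMatrix(genes, prob), n_boot, smoothing)


@dataclass(frozen=True)
class WeightedGraph:
    """Complete graph on the genes with nonnegative -log-probability weights.

    An edge is present iff its weight is finite; the diagonal is +inf.
    """

    gene_ids: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        w = np.array(self.weights, dtype=float)
        n = len(self.gene_ids)
        if w.shape != (n, n):
            raise ValueError("weight matrix shape does not match gene count")
        if not np.array_equal(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        finite = np.isfinite(w)
        if np.any(w[finite] < 0):
            raise ValueError("edge weights must be nonnegative")
        np.fill_diagonal(w, np.inf)
        object.__setattr__(self, "weights", w)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def weight(self, a: str, b: str) -> float:
        return float(self.weights[self.index(a), self.index(b)])

    @classmethod
    def from_unit_edges(cls, gene_ids, edges) -> "WeightedGraph":
        """Unit-weight graph over an explicit undirected edge set."""
        gene_ids = tuple(gene_ids)
        idx = {g: i for i, g in enumerate(gene_ids)}
        w = np.full((len(gene_ids), len(gene_ids)), np.inf)
        for a, b in edges:
            w[idx[a], idx[b]] = w[idx[b], idx[a]] = 1.0
        return cls(gene_ids, w)


def default_probability_floor(n_boot: int) -> float:
    return 1.0 / (10.0 * n_boot)


def to_weighted_graph(result: DirectnessResult,
                      probability_floor: float | None = None) -> WeightedGraph:
    """Transform edge probabilities p to weights -log(max(p, floor)).

    The graph stays complete: improbable edges get large finite weights
    rather than being removed, since the shortest-path objective needs the
    log of a probability, not a pruned topology.
    """
    if probability_floor is None:
        probability_floor = default_probability_floor(result.n_boot)
    p = result.probability.values.copy()
    n = p.shape[0]
    off = ~np.eye(n, dtype=bool)
    if probability_floor <= 0 and np.any(p[off] <= 0):
        raise ValueError(
            "zero probability of directness maps to infinite weight; "
            "enable laplace smoothing or set a positive probability_floor"
        )
    p_eff = np.maximum(p, probability_floor)
    with np.errstate(divide="ignore"):
        w = -np.log(p_eff)
    w[~off] = np.inf
    return WeightedGraph(result.gene_ids, np.maximum(w, 0.0))
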