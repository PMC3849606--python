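"""Scoring inferred pathways against a ground-truth network.

The reference for each (root, target) query is the *true path*: the
fewest-hop path through the (undirected view of the) ground-truth network.
Inferred paths are scored edge-wise (edges as unordered pairs) and
node-wise (interior nodes only — the root and target are inputs to the
query, not inferences).  Precision is tp/(tp+fp) and recall tp/(tp+fn);
precision is preferred over specificity because the count of true-negative
edges dwarfs the handful of edges on any path.  Only query pairs whose true
path is longer than a single edge contribute to reports, which keeps the
node-wise metrics meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dpi import WeightedGraph
from .io import Path, RegulatoryNetwork
from .paths import dijkstra

__all__ = [
    "PathScore",
    "EvaluationReport",
    "CorrelationResult",
    "true_path",
    "score_path",
    "specificity",
    "cyclicity",
    "random_baseline",
    "probability_performance_correlation",
    "evaluate_paths",
]

_LEVELS = ("edge-wise", "node-wise")


@dataclass(frozen=True)
class PathScore:
    tp: int
    fp: int
    fn: int
    level: str

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else 0.0


def specificity(tn: int, fp: int) -> float:
    """tn/(tn+fp); kept for completeness but excluded from reports."""
    return tn / (tn + fp) if tn + fp > 0 else 0.0


def true_path(truth: RegulatoryNetwork, root: str, target: str) -> Path | None:
    """Fewest-hop path through the undirected ground truth; None if unreachable."""
    for node in (root, target):
        if node not in truth.gene_ids:
            raise KeyError(f"unknown gene {node!r}")
    und = truth.undirected_view()
    graph = WeightedGraph.from_unit_edges(und.gene_ids, und.edges)
    return dijkstra(graph, root).path_to(target)


def score_path(inferred: Path, truth_path: Path, level: str) -> PathScore:
    """Count tp/fp/fn between an inferred and a true path at one level."""
    if level not in _LEVELS:
        raise ValueError(f"level must be one of {_LEVELS}")
    if level == "edge-wise":
        inf_items: frozenset = inferred.edge_set()
        true_items: frozenset = truth_path.edge_set()
    else:
        inf_items = inferred.interior_nodes()
        true_items = truth_path.interior_nodes()
    tp = len(inf_items & true_items)
    return PathScore(tp=tp, fp=len(inf_items) - tp, fn=len(true_items) - tp, level=level)


def cyclicity(truth: RegulatoryNetwork) -> float:
    """Fraction of directed edges that are back edges in a depth-first search.

    DFS starts from every unvisited node in label order and explores
    neighbours in label order; an edge into a node currently on the DFS
    stack is a back edge (it closes a directed cycle).  A DAG scores 0.
    """
    if not truth.directed:
        raise ValueError("cyclicity is defined on the directed network")
    if truth.n_edges == 0:
        return 0.0
    succ: dict[str, list[str]] = {g: [] for g in truth.gene_ids}
    for a, b in truth.edges:
        succ[a].append(b)
    for a in succ:
        succ[a].sort()
    color: dict[str, int] = {g: 0 for g in truth.gene_ids}  # 0 new, 1 on stack, 2 done
    back = 0
    for start in sorted(truth.gene_ids):
        if color[start] != 0:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        color[start] = 1
        while stack:
            node, i = stack[-1]
            if i < len(succ[node]):
                stack[-1] = (node, i + 1)
                nxt = succ[node][i]
                if color[nxt] == 1:
                    back += 1
                elif color[nxt] == 0:
                    color[nxt] = 1
                    stack.append((nxt, 0))
            else:
                color[node] = 2
                stack.pop()
    return back / truth.n_edges


def random_baseline(truth: RegulatoryNetwork, gene_ids, seed: int = 0) -> list[Path]:
    """One uniformly random path per ordered (root, target) pair.

    Path length (edge count) is drawn uniformly from [1, L_max] where
    L_max is the longest true-path edge count in the network; intermediate
    nodes are distinct and drawn uniformly, independent of the graph.
    Pairs without a defined true path are skipped.
    """
    gene_ids = tuple(gene_ids)
    if len(gene_ids) < 3:
        raise ValueError("need at least 3 genes for a random-path baseline")
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str, int]] = []
    l_max = 0
    for root in sorted(gene_ids):
        for target in sorted(gene_ids):
            if root == target:
                continue
            tpath = true_path(truth, root, target)
            if tpath is None:
                continue
            pairs.append((root, target, tpath.n_edges))
            l_max = max(l_max, tpath.n_edges)
    out: list[Path] = []
    for root, target, _ in pairs:
        cap = min(l_max, len(gene_ids) - 1)
        length = int(rng.integers(1, cap + 1))
        others = [g for g in gene_ids if g not in (root, target)]
        inter = list(rng.choice(others, size=length - 1, replace=False)) if length > 1 else []
        out.append(Path((root, *inter, target)))
    return out


@dataclass(frozen=True)
class CorrelationResult:
    value: float
    defined: bool


@dataclass(frozen=True)
class EvaluationReport:
    """Per-query scores plus network-level summary quantities.

    ``scores`` has one row per (root, target, level) for queries whose true
    path has at least 2 edges, with tp/fp/fn, precision, recall, the true
    path length and the inferred path's joint probability (NaN if absent).
    """

    scores: pd.DataFrame
    cyclicity: float
    n_skipped: int = 0

    def correlation(self) -> CorrelationResult:
        return probability_performance_correlation(self)

    def mean_metric(self, level: str, metric: str) -> float:
        sub = self.scores[self.scores["level"] == level]
        return float(sub[metric].mean()) if len(sub) else math.nan


def evaluate_paths(truth: RegulatoryNetwork, paths: list[Path]) -> EvaluationReport:
    """Score a batch of inferred paths against the ground-truth network."""
    rows = []
    skipped = 0
    for p in paths:
        tpath = true_path(truth, p.root, p.target)
        if tpath is None or tpath.n_edges < 2:
            skipped += 1
            continue
        for level in _LEVELS:
            s = score_path(p, tpath, level)
            rows.append({
                "root": p.root, "target": p.target, "level": level,
                "tp": s.tp, "fp": s.fp, "fn": s.fn,
                "precision": s.precision, "recall": s.recall,
                "true_path_length": tpath.n_edges,
                "probability": p.probability if p.probability is not None else math.nan,
            })
    scores = pd.DataFrame(rows, columns=["root", "target", "level", "tp", "fp", "fn",
                                         "precision", "recall", "true_path_length",
                                         "probability"])
    return EvaluationReport(scores=scores, cyclicity=cyclicity(truth), n_skipped=skipped)


def probability_performance_correlation(report: EvaluationReport) -> CorrelationResult:
    """Pearson correlation of path probability with (precision + recall)/2.

    Computed across contributing queries at the edge-wise level; flagged
    undefined (NaN) when either vector is constant.
    """
    sub = report.scores[(report.scores["level"] == "edge-wise")
                        & report.scores["probability"].notna()]
    if len(sub) < 3:
        raise ValueError("need at least 3 contributing query pairs")
    prob = sub["probability"].to_numpy()
    perf = ((sub["precision"] + sub["recall"]) / 2.0).to_numpy()
    if np.ptp(prob) == 0 or np.ptp(perf) == 0:
        return CorrelationResult(math.nan, defined=False)
    r, _ = stats.pearsonr(prob, perf)
    return CorrelationResult(float(r), defined=True)
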