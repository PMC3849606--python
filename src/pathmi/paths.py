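"""Single-source shortest paths and most-probable pathway ranking.

Because the edge weights are negative logs of probabilities they are
nonnegative, so Dijkstra's algorithm applies and every shortest path is
automatically simple.  The path minimising the summed weight is exactly the
path maximising the product of edge directness probabilities.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

from .dpi import DirectnessResult, WeightedGraph, default_probability_floor, to_weighted_graph
from .io import Path

__all__ = [
    "ShortestPathResult",
    "dijkstra",
    "most_probable_path",
    "rank_paths",
]


@dataclass(frozen=True)
class ShortestPathResult:
    """Predecessor tree and distances from a fixed root gene."""

    root: str
    predecessor: dict[str, str | None]
    distance: dict[str, float]

    def path_to(self, target: str) -> Path | None:
        """Reconstruct the shortest path to ``target``; None if unreachable."""
        if target not in self.distance:
            raise KeyError(f"unknown gene {target!r}")
        if not math.isfinite(self.distance[target]):
            return None
        nodes = [target]
        while nodes[-1] != self.root:
            prev = self.predecessor[nodes[-1]]
            assert prev is not None
            nodes.append(prev)
        return Path(tuple(reversed(nodes)), total_weight=self.distance[target])


def dijkstra(graph: WeightedGraph, root: str) -> ShortestPathResult:
    """Binary-heap Dijkstra with deterministic tie-breaking.

    Among equal-weight shortest paths the lexicographically smallest
    predecessor label wins, so reconstructed paths are reproducible.
    """
    i_root = graph.index(root)  # raises KeyError on unknown root
    genes = graph.gene_ids
    dist = {g: math.inf for g in genes}
    pred: dict[str, str | None] = {g: None for g in genes}
    dist[root] = 0.0
    done: set[str] = set()
    heap: list[tuple[float, str]] = [(0.0, root)]
    while heap:
        d, u = heapq.heappop(heap)
        if u in done or d > dist[u]:
            continue
        done.add(u)
        iu = graph.index(u)
        for iv, g_v in enumerate(genes):
            if g_v in done:
                continue
            w = graph.weights[iu, iv]
            if not math.isfinite(w):
                continue
            nd = d + w
            if nd < dist[g_v]:
                dist[g_v] = nd
                pred[g_v] = u
                heapq.heappush(heap, (nd, g_v))
            elif nd == dist[g_v] and pred[g_v] is not None and u < pred[g_v]:
                pred[g_v] = u
    return ShortestPathResult(root, pred, dist)


def _hop_capped_search(graph: WeightedGraph, root: str, target: str,
                       max_edges: int) -> tuple[float, tuple[str, ...]] | None:
    """Dijkstra over layered (node, hops) states for a hop-capped search."""
    genes = graph.gene_ids
    best: dict[tuple[str, int], float] = {(root, 0): 0.0}
    pred: dict[tuple[str, int], tuple[str, int] | None] = {(root, 0): None}
    heap: list[tuple[float, str, int]] = [(0.0, root, 0)]
    result: tuple[float, tuple[str, int]] | None = None
    while heap:
        d, u, h = heapq.heappop(heap)
        if d > best.get((u, h), math.inf):
            continue
        if u == target and (result is None or d < result[0]):
            result = (d, (u, h))
        if h == max_edges:
            continue
        iu = graph.index(u)
        for iv, v in enumerate(genes):
            w = graph.weights[iu, iv]
            if not math.isfinite(w):
                continue
            state = (v, h + 1)
            nd = d + w
            if nd < best.get(state, math.inf):
                best[state] = nd
                pred[state] = (u, h)
                heapq.heappush(heap, (nd, v, h + 1))
    if result is None:
        return None
    d, state = result
    nodes = [state[0]]
    while pred[state] is not None:
        state = pred[state]  # type: ignore[assignment]
        nodes.append(state[0])
    nodes.reverse()
    if len(set(nodes)) != len(nodes):  # revisits can occur only via zero-weight cycles
        return None
    return d, tuple(nodes)


def most_probable_path(result: DirectnessResult, root: str, target: str,
                       probability_floor: float | None = None,
                       max_edges: int | None = None) -> Path:
    """Maximum joint-probability simple path between two genes.

    Under the independence assumption the probability of a path is the
    product of its edges' directness probabilities; the returned path
    maximises that product (optionally under a hop cap ``max_edges``).
    """
    if root == target:
        raise ValueError("root and target must differ")
    if probability_floor is None:
        probability_floor = default_probability_floor(result.n_boot)
    graph = to_weighted_graph(result, probability_floor)
    graph.index(root)
    graph.index(target)
    if max_edges is not None:
        found = _hop_capped_search(graph, root, target, max_edges)
        if found is None:
            raise ValueError(f"no path from {root!r} to {target!r} within {max_edges} edges")
        weight, nodes = found
    else:
        sp = dijkstra(graph, root)
        path = sp.path_to(target)
        if path is None:
            raise ValueError(f"no path from {root!r} to {target!r}")
        weight, nodes = path.total_weight, path.nodes
    # recompute probability as the product of (floored) edge probabilities so
    # the probability/weight duality is exact
    prob = 1.0
    for a, b in zip(nodes[:-1], nodes[1:]):
        prob *= max(result.probability.get(a, b), probability_floor)
    return Path(nodes, probability=prob, total_weight=-math.log(prob) if prob > 0 else math.inf)


def rank_paths(result: DirectnessResult, pairs: list[tuple[str, str]],
               probability_floor: float | None = None,
               max_edges: int | None = None) -> list[Path]:
    """Most-probable path per (root, target) pair, ranked by probability.

    Sorted by descending joint probability; ties broken by (root, target)
    label order, so the ranking does not depend on the input pair order.
    """
    paths = [most_probable_path(result, r, t, probability_floor, max_edges) for r, t in pairs]
    return sorted(paths, key=lambda p: (-(p.probability or 0.0), p.root, p.target))
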