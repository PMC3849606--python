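"""Synthetic regulatory networks and expression data for testing inference.

Stands in for in-silico benchmark generators: builds ground-truth networks
of controllable topology and cyclicity, then simulates expression with a
bounded (sigmoidal) regulatory response plus Gaussian noise, giving data
with the nonlinear dependence structure that motivates mutual information
over correlation.  Cyclic components are resolved by synchronous iteration
from a random initial state rather than an ODE steady state — cheap,
reproducible, and sufficient to create multi-channel dependence.

Also provides a closed-form Gaussian tree model (pairwise correlation =
product of edge correlations along the tree path; MI = -0.5 log(1 - rho^2))
as an analytic fixture on which DPI pruning provably recovers the tree, and
the four-node two-channel cycle on which "skipping" — inferring a shortcut
edge across parallel influence channels — is expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, RegulatoryNetwork, SymmetricGeneMatrix

__all__ = [
    "SimulationConfig",
    "generate_network",
    "simulate_expression",
    "gaussian_tree_model",
    "two_channel_cycle_network",
]

_TOPOLOGIES = ("chain", "tree", "random-with-cycles")
_CYCLE_ROUNDS = 10


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated dataset.

    Defaults describe a strong-signal regime: a unit-variance source signal
    pushed through a tanh response with gain ``regulation_strength`` and
    corrupted by additive noise of standard deviation ``noise_sd``.
    """

    n_genes: int = 10
    topology: str = "chain"
    cycle_fraction: float = 0.0
    n_samples: int = 400
    regulation_strength: float = 1.5
    noise_sd: float = 0.2
    nonlinearity: str = "sigmoidal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        if self.topology not in _TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0.0 <= self.cycle_fraction <= 1.0:
            raise ValueError("cycle_fraction must be in [0, 1]")
        if self.cycle_fraction > 0 and self.topology != "random-with-cycles":
            raise ValueError(f"topology {self.topology!r} is acyclic; cycle_fraction must be 0")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")
        if self.regulation_strength <= 0 or self.noise_sd <= 0:
            raise ValueError("regulation_strength and noise_sd must be positive")
        if self.nonlinearity not in ("linear", "sigmoidal"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


def _gene_labels(n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"G{i:0{width}d}" for i in range(1, n + 1))


def generate_network(config: SimulationConfig) -> RegulatoryNetwork:
    """Ground-truth directed network of the configured topology.

    chain: G1 -> G2 -> ... -> Gn.  tree: each later gene regulated by a
    uniformly chosen earlier gene.  random-with-cycles: a tree plus
    round(cycle_fraction * (n - 1)) extra edges, each from a node back to
    one of its tree ancestors so every extra edge closes a directed cycle.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_genes
    genes = _gene_labels(n)
    if config.topology == "chain":
        edges = {(genes[i], genes[i + 1]) for i in range(n - 1)}
        return RegulatoryNetwork(genes, frozenset(edges), directed=True)
    parent = [-1] * n
    edges = set()
    for i in range(1, n):
        parent[i] = int(rng.integers(0, i))
        edges.add((genes[parent[i]], genes[i]))
    if config.topology == "random-with-cycles":
        n_extra = round(config.cycle_fraction * (n - 1))
        added = 0
        tries = 0
        while added < n_extra and tries < 100 * max(n_extra, 1):
            tries += 1
            v = int(rng.integers(1, n))
            ancestors = []
            u = parent[v]
            while u != -1:
                ancestors.append(u)
                u = parent[u]
            a = ancestors[int(rng.integers(0, len(ancestors)))]
            edge = (genes[v], genes[a])
            if edge not in edges:
                edges.add(edge)
                added += 1
    return RegulatoryNetwork(genes, frozenset(edges), directed=True)


def _response(x: np.ndarray, config: SimulationConfig) -> np.ndarray:
    drive = config.regulation_strength * x
    return np.tanh(drive) if config.nonlinearity == "sigmoidal" else drive


def _topological_order(genes: tuple[str, ...], parents: dict[str, list[str]]) -> list[str] | None:
    indeg = {g: len(parents[g]) for g in genes}
    children: dict[str, list[str]] = {g: [] for g in genes}
    for g, ps in parents.items():
        for p in ps:
            children[p].append(g)
    ready = sorted(g for g in genes if indeg[g] == 0)
    order = []
    while ready:
        g = ready.pop(0)
        order.append(g)
        for c in sorted(children[g]):
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
        ready.sort()
    return order if len(order) == len(genes) else None


def simulate_expression(network: RegulatoryNetwork,
                        config: SimulationConfig) -> ExpressionMatrix:
    """Simulate expression from a ground-truth network.

    Source genes (no regulators) draw from a standard normal; each
    regulated gene is ``response(mean of its parents) + noise``.  Acyclic
    networks are evaluated once in topological order; cyclic ones are
    iterated synchronously for a fixed number of rounds from a random
    initial state, with source values and noise drawn once and held fixed.
    """
    genes = network.gene_ids
    n, m = len(genes), config.n_samples
    parents: dict[str, list[str]] = {g: [] for g in genes}
    for a, b in network.edges:
        parents[b].append(a)
    for g in parents:
        parents[g].sort()
    idx = {g: i for i, g in enumerate(genes)}
    rng_source = np.random.default_rng([config.seed, 1])
    rng_noise = np.random.default_rng([config.seed, 2])
    rng_init = np.random.default_rng([config.seed, 3])
    source = rng_source.standard_normal((n, m))
    noise = rng_noise.standard_normal((n, m)) * config.noise_sd
    order = _topological_order(genes, parents)
    if order is not None:
        x = np.zeros((n, m))
        for g in order:
            i = idx[g]
            if not parents[g]:
                x[i] = source[i]
            else:
                drive = np.mean([x[idx[p]] for p in parents[g]], axis=0)
                x[i] = _response(drive, config) + noise[i]
    else:
        x = rng_init.standard_normal((n, m))
        for i, g in enumerate(genes):
            if not parents[g]:
                x[i] = source[i]
        for _ in range(_CYCLE_ROUNDS):
            new = x.copy()
            for g in genes:
                i = idx[g]
                if parents[g]:
                    drive = np.mean([x[idx[p]] for p in parents[g]], axis=0)
                    new[i] = _response(drive, config) + noise[i]
            x = new
    samples = tuple(f"S{j + 1}" for j in range(m))
    return ExpressionMatrix(genes, samples, x)


def gaussian_tree_model(n_nodes: int = 10, seed: int = 0,
                        rho_range: tuple[float, float] = (0.5, 0.9),
                        ) -> tuple[RegulatoryNetwork, SymmetricGeneMatrix]:
    """Random tree plus its exact Gaussian MI matrix.

    On a Gaussian tree (a Markov random field whose graph is a tree), the
    correlation between two nodes is the product of edge correlations along
    the connecting path, and I = -0.5 log(1 - rho^2).  Because |rho| < 1 on
    every edge, any indirect pair has strictly smaller MI than both edges
    of any triplet routing through a separator — so DPI pruning of this
    matrix recovers exactly the tree edges.
    """
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    rng = np.random.default_rng([seed, 4])
    genes = _gene_labels(n_nodes)
    parent = [-1] * n_nodes
    edges = set()
    for i in range(1, n_nodes):
        parent[i] = int(rng.integers(0, i))
        edges.add((genes[parent[i]], genes[i]))
    rho_edge = {}
    lo, hi = rho_range
    for i in range(1, n_nodes):
        rho_edge[i] = float(rng.uniform(lo, hi))
    # pairwise correlations via path products up the tree
    rho = np.eye(n_nodes)
    def path_to_root(i: int) -> list[int]:
        out = [i]
        while parent[out[-1]] != -1:
            out.append(parent[out[-1]])
        return out
    for i in range(n_nodes):
        pi = path_to_root(i)
        for j in range(i + 1, n_nodes):
            pj = path_to_root(j)
            common = next(v for v in pi if v in set(pj))
            r = 1.0
            for v in pi[:pi.index(common)]:
                r *= rho_edge[v]
            for v in pj[:pj.index(common)]:
                r *= rho_edge[v]
            rho[i, j] = rho[j, i] = r
    mi = -0.5 * np.log(1.0 - rho ** 2, where=~np.eye(n_nodes, dtype=bool),
                       out=np.full((n_nodes, n_nodes), np.nan))
    net = RegulatoryNetwork(genes, frozenset(edges), directed=True)
    return net, SymmetricGeneMatrix(genes, mi)


def two_channel_cycle_network() -> RegulatoryNetwork:
    """Four genes with two parallel channels A->B->D and A->C->D.

    Undirected, this is a 4-cycle.  The summed influence of the two
    channels makes I(A,D) large, so DPI-based inference tends to keep a
    shortcut A-D edge and prune true edges — the documented skipping
    failure mode of triplet-based pruning in cycles.
    """
    genes = ("A", "B", "C", "D")
    edges = frozenset({("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")})
    return RegulatoryNetwork(genes, edges, directed=True)
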