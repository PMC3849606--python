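"""Domain containers and plain-text I/O.

Expression matrices travel as labelled TSV (genes in rows by default),
networks as whitespace-delimited edge lists, symmetric gene-by-gene
matrices (mutual information, edge probabilities) as labelled TSV, and
inferred paths as a sorted TSV table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SymmetricGeneMatrix",
    "RegulatoryNetwork",
    "Path",
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_matrix",
    "write_matrix",
    "write_paths",
]

_DUALITY_TOL = 1e-9


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene-by-sample real-valued expression measurements.

    Rows are genes, columns are samples.  Values are arbitrary expression
    units; only their joint empirical distribution matters downstream.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene)]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class SymmetricGeneMatrix:
    """Symmetric gene-by-gene matrix (MI estimates or edge probabilities).

    The diagonal is a NaN sentinel unless ``diagonal_defined`` — pairwise
    quantities between a gene and itself never enter triplet comparisons.
    """

    gene_ids: tuple[str, ...]
    values: np.ndarray
    diagonal_defined: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        values = np.array(self.values, dtype=float)
        n = len(self.gene_ids)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} genes")
        _check_unique(self.gene_ids, "gene")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(values[off], values.T[off], rtol=0, atol=1e-12, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        # canonicalise: exact symmetry regardless of float noise in input
        values = np.where(off, (values + values.T) / 2.0, values)
        if not self.diagonal_defined:
            np.fill_diagonal(values, np.nan)
        object.__setattr__(self, "values", values)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def offdiagonal(self) -> np.ndarray:
        """Flat array of the upper-triangle (i < j) entries."""
        iu = np.triu_indices(self.n_genes, k=1)
        return self.values[iu]

    def get(self, a: str, b: str) -> float:
        i, j = self.gene_ids.index(a), self.gene_ids.index(b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.gene_ids))


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Ground-truth or inferred regulatory network as an edge set."""

    gene_ids: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    directed: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        edges = frozenset((str(a), str(b)) for a, b in self.edges)
        if not self.directed:
            edges = frozenset(tuple(sorted(e)) for e in edges)
        object.__setattr__(self, "edges", edges)
        _check_unique(self.gene_ids, "gene")
        nodes = set(self.gene_ids)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r} is not allowed")
            if a not in nodes or b not in nodes:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown gene")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def undirected_view(self) -> "RegulatoryNetwork":
        """Collapse (a,b)/(b,a) into a single undirected edge."""
        return RegulatoryNetwork(self.gene_ids, self.edges, directed=False)

    def undirected_edge_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.edges)

    def has_undirected_edge(self, a: str, b: str) -> bool:
        return (a, b) in self.edges or (b, a) in self.edges

    def neighbors(self, node: str) -> list[str]:
        """Undirected neighbourhood, sorted by label."""
        out = {b for a, b in self.edges if a == node} | {a for a, b in self.edges if b == node}
        return sorted(out)


@dataclass(frozen=True)
class Path:
    """A simple path through the gene graph.

    ``probability`` is the joint probability that every edge on the path is
    a direct regulatory interaction; ``total_weight`` is its negative log.
    Either may be None (e.g. for unit-weight paths extracted from a
    comparator network).
    """

    nodes: tuple[str, ...]
    probability: float | None = None
    total_weight: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(str(n) for n in self.nodes))
        if len(self.nodes) == 0:
            raise ValueError("a path needs at least one node")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path repeats a node (must be simple)")
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"path probability {self.probability} outside [0, 1]")
        if self.total_weight is not None and self.total_weight < -_DUALITY_TOL:
            raise ValueError(f"negative total weight {self.total_weight}")
        if self.probability is not None and self.total_weight is not None:
            if self.probability > 0 and abs(self.total_weight + math.log(self.probability)) > 1e-6:
                raise ValueError("total_weight inconsistent with -log(probability)")

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.nodes[:-1], self.nodes[1:]))

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    @property
    def root(self) -> str:
        return self.nodes[0]

    @property
    def target(self) -> str:
        return self.nodes[-1]

    def edge_set(self) -> frozenset[frozenset[str]]:
        """Edges as unordered pairs (inference is direction-blind)."""
        return frozenset(frozenset(e) for e in self.edges)

    def interior_nodes(self) -> frozenset[str]:
        return frozenset(self.nodes[1:-1])


def _check_unique(labels: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {kind} label {lab!r}")
        seen.add(lab)


# ---------------------------------------------------------------------------
# readers / writers


def read_expression(path, orientation: str = "genes-in-rows") -> ExpressionMatrix:
    """Read a TSV expression matrix (one header row, one label column).

    ``orientation='genes-in-columns'`` transposes on read so the result is
    always genes-by-samples.
    """
    if orientation not in ("genes-in-rows", "genes-in-columns"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError("no samples: the data region of the file is empty")
    _check_unique([str(i) for i in df.index], "row")
    _check_unique([str(c) for c in df.columns], "column")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                values[i, j] = float(raw[i, j])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric cell {raw[i, j]!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                ) from None
    genes, samples = tuple(map(str, df.index)), tuple(map(str, df.columns))
    if orientation == "genes-in-columns":
        return ExpressionMatrix(samples, genes, values.T)
    return ExpressionMatrix(genes, samples, values)


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", index_label="gene")


def read_network(path) -> RegulatoryNetwork:
    """Read a 2/3-column edge list; a 3rd column (sign/weight) is ignored."""
    edges: set[tuple[str, str]] = set()
    nodes: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected at least 2 columns")
            a, b = fields[0], fields[1]
            if a == b:
                raise ValueError(f"line {lineno}: self-loop on {a!r}")
            for n in (a, b):
                if n not in seen:
                    seen.add(n)
                    nodes.append(n)
            edges.add((a, b))
    return RegulatoryNetwork(tuple(nodes), frozenset(edges), directed=True)


def write_network(net: RegulatoryNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{b}\n")


def read_matrix(path) -> SymmetricGeneMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("matrix row and column labels disagree")
    return SymmetricGeneMatrix(tuple(map(str, df.index)), df.to_numpy(dtype=float))


def write_matrix(mat: SymmetricGeneMatrix, path) -> None:
    mat.to_dataframe().to_csv(path, sep="\t", index_label="gene")


PATHS_HEADER = ("root", "target", "path", "probability", "total_weight")


def write_paths(paths: Iterable[Path], path) -> None:
    """Write paths as TSV sorted by descending probability."""
    rows = sorted(paths, key=lambda p: (-(p.probability if p.probability is not None else 0.0),
                                        p.root, p.target))
    with open(path, "w") as fh:
        fh.write("\t".join(PATHS_HEADER) + "\n")
        for p in rows:
            if p.probability is None:
                raise ValueError("write_paths requires paths with defined probability")
            weight = p.total_weight if p.total_weight is not None else (
                -math.log(p.probability) if p.probability > 0 else math.inf
            )
            fh.write(
                f"{p.root}\t{p.target}\t{'->'.join(p.nodes)}\t"
                f"{p.probability:.10g}\t{weight:.10g}\n"
            )
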