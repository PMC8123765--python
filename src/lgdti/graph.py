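"""Bipartite drug-protein interaction graph and its matrix views.

Node ordering is fixed: drugs occupy rows ``0..n-1`` (lexicographically
sorted drug ids) followed by proteins in rows ``n..n+m-1`` (sorted protein
ids).  All matrix builders respect this ordering, so the adjacency has the
block form ``[[0, R], [R.T, 0]]`` with ``R`` the n-by-m interaction matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BipartiteGraph:
    """Undirected bipartite interaction graph.

    Edges are stored once, drug-first: ``(drug_index, protein_index)``
    with the drug index in ``[0, n)`` and the protein index in ``[0, m)``.
    """

    drug_ids: tuple[str, ...]
    protein_ids: tuple[str, ...]
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        n, m = len(self.drug_ids), len(self.protein_ids)
        if len(set(self.drug_ids)) != n or len(set(self.protein_ids)) != m:
            raise ValueError("duplicate node ids")
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < m):
                raise ValueError(f"edge ({i}, {j}) out of range for n={n}, m={m}")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_drugs + self.n_proteins

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def drug_node(self, drug_index: int) -> int:
        """Global node index of a drug."""
        return drug_index

    def protein_node(self, protein_index: int) -> int:
        """Global node index of a protein (offset by the drug count)."""
        return self.n_drugs + protein_index

    def sorted_edges(self) -> list[tuple[int, int]]:
        """Canonical (sorted) edge order used for incidence columns."""
        return sorted(self.edges)

    def adjacency_lists(self) -> list[np.ndarray]:
        """Per-node sorted neighbor arrays in global node indices (no self-loops)."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.sorted_edges():
            u, v = self.drug_node(i), self.protein_node(j)
            nbrs[u].append(v)
            nbrs[v].append(u)
        return [np.asarray(sorted(a), dtype=np.int64) for a in nbrs]

    def degrees(self) -> np.ndarray:
        """Node degrees excluding self-loops."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[self.drug_node(i)] += 1
            deg[self.protein_node(j)] += 1
        return deg

    def remove_edges(self, pairs: set[tuple[int, int]] | frozenset[tuple[int, int]]) -> "BipartiteGraph":
        """Graph with the given (drug_index, protein_index) edges removed; node sets kept."""
        return BipartiteGraph(self.drug_ids, self.protein_ids, self.edges - frozenset(pairs))


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Dense 0/1 adjacency over the n+m nodes; optionally with unit diagonal."""

    values: np.ndarray
    self_loops: bool


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Symmetric normalization D^{-1/2} (A + I) D^{-1/2} of the self-looped adjacency."""

    values: np.ndarray


@dataclass(frozen=True)
class IncidenceMatrix:
    """Node-by-edge 0/1 incidence; each column marks one edge's two endpoints."""

    values: np.ndarray


def build_graph(edge_records: list[tuple[str, str]]) -> BipartiteGraph:
    """Build a :class:`BipartiteGraph` from (drug_id, protein_id) records.

    Duplicate records collapse to a single edge (logged).  Node ids are the
    sorted unique ids from the records.
    """
    if not edge_records:
        raise ValueError("empty edge list")
    for lineno, rec in enumerate(edge_records, start=1):
        if len(rec) != 2 or not rec[0] or not rec[1]:
            raise ValueError(f"malformed record at line {lineno}: {rec!r}")
    drug_ids = tuple(sorted({d for d, _ in edge_records}))
    protein_ids = tuple(sorted({p for _, p in edge_records}))
    d_index = {d: i for i, d in enumerate(drug_ids)}
    p_index = {p: j for j, p in enumerate(protein_ids)}
    edges = frozenset((d_index[d], p_index[p]) for d, p in edge_records)
    n_dup = len(edge_records) - len(edges)
    if n_dup:
        logger.info("collapsed %d duplicate edge records", n_dup)
    return BipartiteGraph(drug_ids, protein_ids, edges)


def build_adjacency(g: BipartiteGraph, add_self_loops: bool) -> AdjacencyMatrix:
    """Dense adjacency of the bipartite graph, optionally A + I."""
    size = g.n_nodes
    a = np.zeros((size, size), dtype=np.float64)
    for i, j in g.edges:
        u, v = g.drug_node(i), g.protein_node(j)
        a[u, v] = 1.0
        a[v, u] = 1.0
    if add_self_loops:
        np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(values=a, self_loops=add_self_loops)


def normalize_adjacency(a: AdjacencyMatrix) -> NormalizedAdjacency:
    """Symmetric degree normalization: entry (i, j) becomes A(i,j)/sqrt(d_i d_j)."""
    deg = a.values.sum(axis=1)
    if np.any(deg == 0):
        raise ValueError("isolated node; enable self-loops")
    inv_sqrt = 1.0 / np.sqrt(deg)
    norm = a.values * inv_sqrt[:, None] * inv_sqrt[None, :]
    return NormalizedAdjacency(values=norm)


def build_incidence(g: BipartiteGraph) -> IncidenceMatrix:
    """Node-by-edge incidence matrix, columns in canonical edge order."""
    edges = g.sorted_edges()
    b = np.zeros((g.n_nodes, len(edges)), dtype=np.float64)
    for col, (i, j) in enumerate(edges):
        b[g.drug_node(i), col] = 1.0
        b[g.protein_node(j), col] = 1.0
    return IncidenceMatrix(values=b)
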