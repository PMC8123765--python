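"""Synthetic fixtures: planted-partition bipartite graphs, random parseable
SMILES, and random protein sequences.

Block structure is the statistical target: intrinsic attributes carry no
block signal, while graph-derived features do, so feature-family orderings
can be exercised without any licensed dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .graph import BipartiteGraph

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class PlantedPartitionSpec:
    n_drugs: int
    n_proteins: int
    n_blocks: int = 2
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if min(self.n_drugs, self.n_proteins, self.n_blocks) < 1:
            raise ValueError("sizes must be positive")


def _block_labels(count: int, n_blocks: int) -> np.ndarray:
    # round-robin so remainders spread evenly
    return np.arange(count) % n_blocks


def synth_graph(
    spec: PlantedPartitionSpec, max_retries: int = 10
) -> tuple[BipartiteGraph, np.ndarray, np.ndarray]:
    """Planted-partition bipartite graph.

    Returns the graph plus per-drug and per-protein block labels (aligned
    with the graph's sorted id order).  A drug-protein pair in the same
    block links with probability p_in, otherwise p_out.
    """
    width = max(4, len(str(max(spec.n_drugs, spec.n_proteins))))
    drug_ids = tuple(f"D{i:0{width}d}" for i in range(spec.n_drugs))
    protein_ids = tuple(f"P{j:0{width}d}" for j in range(spec.n_proteins))
    drug_blocks = _block_labels(spec.n_drugs, spec.n_blocks)
    protein_blocks = _block_labels(spec.n_proteins, spec.n_blocks)
    same = drug_blocks[:, None] == protein_blocks[None, :]
    probs = np.where(same, spec.p_in, spec.p_out)

    rng = np.random.default_rng(spec.seed)
    for attempt in range(max_retries):
        mask = rng.random((spec.n_drugs, spec.n_proteins)) < probs
        if mask.any():
            break
        warnings.warn("planted-partition draw produced no edges; retrying")
    else:
        raise ValueError("no edges after retries; raise p_in/p_out or sizes")

    edges = frozenset(zip(*np.nonzero(mask)))
    g = BipartiteGraph(drug_ids, protein_ids, frozenset((int(i), int(j)) for i, j in edges))
    return g, drug_blocks, protein_blocks


_CHAIN_ATOMS = ["C", "C", "C", "N", "O"]
_SUFFIXES = [
    "",
    "c1ccccc1",
    "C1CCCCC1",
    "c1ccncc1",
    "C(=O)O",
    "C(=O)N",
    "C#N",
    "Cl",
    "Br",
    "O",
    "N",
    "S",
]


def synth_molecules(n: int, seed: int = 0, width: int | None = None) -> list[tuple[str, str]]:
    """n deterministic, RDKit-parseable SMILES built from a small fragment
    vocabulary (alkyl/heteroatom chains plus common rings and groups)."""
    rng = np.random.default_rng(seed)
    width = width or max(4, len(str(n)))
    table: list[tuple[str, str]] = []
    while len(table) < n:
        length = int(rng.integers(1, 9))
        chain = "C" + "".join(
            _CHAIN_ATOMS[rng.integers(len(_CHAIN_ATOMS))] for _ in range(length - 1)
        )
        smiles = chain + _SUFFIXES[rng.integers(len(_SUFFIXES))]
        if Chem.MolFromSmiles(smiles) is None:  # vocabulary should never fail
            logger.warning("rejected generated SMILES %r", smiles)
            continue
        table.append((f"D{len(table):0{width}d}", smiles))
    return table


def synth_proteins(
    n: int,
    length_range: tuple[int, int] = (100, 300),
    seed: int = 0,
    k: int = 3,
    width: int | None = None,
) -> list[tuple[str, str]]:
    """n random sequences, lengths uniform in length_range, residues uniform
    over the 20 standard amino acids."""
    lo, hi = length_range
    if lo < k:
        raise ValueError(f"minimum length {lo} is below featurizer k={k}")
    rng = np.random.default_rng(seed)
    width = width or max(4, len(str(n)))
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(AMINO_ACIDS[c] for c in rng.integers(0, 20, size=length))
        records.append((f"P{i:0{width}d}", seq))
    return records
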