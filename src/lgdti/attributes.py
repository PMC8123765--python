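"""Intrinsic node attributes.

Drugs: folded Morgan (circular) fingerprint bit vectors computed with RDKit.
Proteins: overlapping k-mer composition over a 4-group reduced amino-acid
alphabet, giving a 4^k-dimensional frequency vector (64 for k=3).

Both live in one node-attribute matrix, drugs first then proteins, so the
two vector families must share a common width (64 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from rdkit import RDLogger

from .graph import BipartiteGraph

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

#: 4-group reduced amino-acid alphabet:
#: 0 hydrophobic, 1 polar, 2 basic, 3 acidic.
RESIDUE_GROUPS: dict[str, int] = {
    **{r: 0 for r in "AVLIMFWP"},
    **{r: 1 for r in "GSTCNQY"},
    **{r: 2 for r in "RKH"},
    **{r: 3 for r in "DE"},
}

N_GROUPS = 4


def reduce_residue(residue: str) -> int:
    """Map a one-letter amino-acid code (case-insensitive) to its group index."""
    try:
        return RESIDUE_GROUPS[residue.upper()]
    except KeyError:
        raise KeyError(f"non-standard residue code: {residue!r}") from None


def _reduce_sequence(sequence: str) -> np.ndarray:
    """Reduce a sequence to group indices, dropping non-standard residues."""
    groups = [RESIDUE_GROUPS.get(ch) for ch in sequence.upper()]
    n_dropped = sum(g is None for g in groups)
    if n_dropped:
        logger.warning("dropped %d non-standard residues from sequence", n_dropped)
    return np.asarray([g for g in groups if g is not None], dtype=np.int64)


def kmer_features(sequence: str, k: int = 3, protein_id: str | None = None) -> np.ndarray:
    """Frequency vector of reduced k-mers over all overlapping windows.

    The slot for a k-mer with group digits (g1, ..., gk) is the big-endian
    base-4 integer sum(g_i * 4**(k-i)); entries sum to 1 for any sequence
    whose cleaned length is at least k.
    """
    if k < 1:
        raise ValueError("k must be positive")
    reduced = _reduce_sequence(sequence)
    n_windows = len(reduced) - k + 1
    if n_windows < 1:
        who = protein_id or "<unnamed>"
        raise ValueError(f"sequence too short for k={k}: protein {who}")
    idx = np.zeros(n_windows, dtype=np.int64)
    for offset in range(k):
        idx = idx * N_GROUPS + reduced[offset : offset + n_windows]
    counts = np.bincount(idx, minlength=N_GROUPS**k).astype(np.float64)
    return counts / n_windows


def drug_fingerprint(
    smiles: str,
    radius: int = 2,
    n_bits: int = 64,
    drug_id: str | None = None,
) -> np.ndarray:
    """Folded Morgan fingerprint as a 0/1 vector of length ``n_bits``."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = drug_id or "<unnamed>"
        raise ValueError(f"invalid SMILES for drug {who}: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return np.asarray(fp, dtype=np.float64)


@dataclass(frozen=True)
class AttributeResult:
    """Node attribute matrix plus the (possibly filtered) graph it indexes."""

    values: np.ndarray  # (n+m) x d_attr, drug rows first
    graph: BipartiteGraph
    dropped_drugs: tuple[str, ...] = ()


def build_attribute_matrix(
    g: BipartiteGraph,
    smiles_table: dict[str, str],
    fasta_records: dict[str, str],
    d_attr: int = 64,
    radius: int = 2,
    k: int = 3,
    on_bad_smiles: str = "fail",
) -> AttributeResult:
    """Assemble the (n+m) x d_attr matrix X = [X_drugs; X_proteins].

    With ``on_bad_smiles="drop"`` a drug whose SMILES fails to parse is
    removed from the graph together with its edges; ``"fail"`` raises.
    """
    if on_bad_smiles not in ("fail", "drop"):
        raise ValueError(f"unknown on_bad_smiles policy: {on_bad_smiles!r}")
    if N_GROUPS**k != d_attr:
        raise ValueError(
            f"protein k-mer width {N_GROUPS ** k} (k={k}) must equal d_attr={d_attr}"
        )
    missing = [d for d in g.drug_ids if d not in smiles_table]
    missing += [p for p in g.protein_ids if p not in fasta_records]
    if missing:
        raise ValueError(f"attribute missing for node: {', '.join(missing)}")

    drug_rows: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for drug_id in g.drug_ids:
        try:
            drug_rows[drug_id] = drug_fingerprint(
                smiles_table[drug_id], radius=radius, n_bits=d_attr, drug_id=drug_id
            )
        except ValueError:
            if on_bad_smiles == "fail":
                raise
            dropped.append(drug_id)
    if dropped:
        logger.warning("dropped %d drugs with unparseable SMILES: %s", len(dropped), dropped)
        keep = [i for i, d in enumerate(g.drug_ids) if d not in dropped]
        remap = {old: new for new, old in enumerate(keep)}
        g = BipartiteGraph(
            tuple(g.drug_ids[i] for i in keep),
            g.protein_ids,
            frozenset((remap[i], j) for i, j in g.edges if i in remap),
        )

    rows = [drug_rows[d] for d in g.drug_ids]
    rows += [
        kmer_features(fasta_records[p], k=k, protein_id=p) for p in g.protein_ids
    ]
    return AttributeResult(
        values=np.vstack(rows) if rows else np.zeros((0, d_attr)),
        graph=g,
        dropped_drugs=tuple(dropped),
    )
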