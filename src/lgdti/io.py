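"""Readers and writers for the plain-text input formats.

Edge lists and SMILES tables are two-column delimited text (tab or comma);
protein sequences are standard FASTA (record id up to first whitespace).
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO


def _split_line(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [f.strip() for f in line.rstrip("\n").split(sep)]


def read_edge_list(path: str | Path, header: bool = False) -> list[tuple[str, str]]:
    """Read (drug_id, protein_id) records; '#' comment lines are skipped.

    ``header`` explicitly controls whether the first data line is dropped —
    no content sniffing.
    """
    records: list[tuple[str, str]] = []
    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if first and header:
                first = False
                continue
            first = False
            fields = _split_line(line)
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"malformed record at line {lineno} of {path}")
            records.append((fields[0], fields[1]))
    if not records:
        raise ValueError(f"empty edge list: {path}")
    return records


def read_smiles_table(path: str | Path, header: bool = False) -> dict[str, str]:
    """Read a (drug_id, smiles) table into a dict."""
    table: dict[str, str] = {}
    with open(path) as fh:
        first = True
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if first and header:
                first = False
                continue
            first = False
            fields = _split_line(line)
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise ValueError(f"malformed record at line {lineno} of {path}")
            table[fields[0]] = fields[1]
    if not table:
        raise ValueError(f"empty SMILES table: {path}")
    return table


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by FASTA record id (up to first whitespace)."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_edge_list(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for d, p in records:
            fh.write(f"{d}\t{p}\n")


def write_smiles_table(path: str | Path, table: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for drug_id, smiles in table:
            fh.write(f"{drug_id}\t{smiles}\n")


def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for protein_id, seq in records:
            fh.write(f">{protein_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
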