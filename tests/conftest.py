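import numpy as np
import pytest

from lgdti import (
    BipartiteGraph,
    PlantedPartitionSpec,
    build_attribute_matrix,
    build_graph,
    make_pair_set,
    synth_graph,
    synth_molecules,
    synth_proteins,
)


@pytest.fixture
def single_edge_graph():
    """One drug linked to one protein."""
    return build_graph([("d1", "t1")])


@pytest.fixture
def wedge_graph():
    """Two drugs sharing one protein: edges (0,0), (1,0)."""
    return build_graph([("d1", "t1"), ("d2", "t1")])


@pytest.fixture
def star_graph():
    """One drug linked to three proteins (center = node 0)."""
    return build_graph([("d1", "t1"), ("d1", "t2"), ("d1", "t3")])


def random_bipartite(n, m, p, seed):
    rng = np.random.default_rng(seed)
    edges = frozenset(
        (int(i), int(j)) for i, j in zip(*np.nonzero(rng.random((n, m)) < p))
    )
    return BipartiteGraph(
        tuple(f"d{i:03d}" for i in range(n)),
        tuple(f"t{j:03d}" for j in range(m)),
        edges,
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """Small planted-partition fixture with attributes, shared across tests."""
    g, drug_blocks, protein_blocks = synth_graph(
        PlantedPartitionSpec(30, 20, 2, 0.4, 0.03, seed=11)
    )
    mols = dict(synth_molecules(30, seed=12))
    prots = dict(synth_proteins(20, seed=13))
    attrs = build_attribute_matrix(g, mols, prots)
    return {
        "graph": attrs.graph,
        "x": attrs.values,
        "drug_blocks": drug_blocks,
        "protein_blocks": protein_blocks,
        "pairs": make_pair_set(attrs.graph, seed=14),
    }


@pytest.fixture
def fixture_dir(tmp_path):
    """On-disk fixture files for CLI tests."""
    from lgdti.io import write_edge_list, write_fasta, write_smiles_table

    g, _, _ = synth_graph(PlantedPartitionSpec(15, 10, 2, 0.5, 0.05, seed=5))
    mols = synth_molecules(15, seed=6)
    prots = synth_proteins(10, seed=7)
    write_edge_list(
        tmp_path / "edges.tsv",
        [(g.drug_ids[i], g.protein_ids[j]) for i, j in g.sorted_edges()],
    )
    write_smiles_table(tmp_path / "drugs.smi", mols)
    write_fasta(tmp_path / "proteins.fasta", prots)
    return tmp_path
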