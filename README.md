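# lgdti

Drug–target interaction (DTI) prediction on a bipartite drug–protein graph.
Each node gets three representations:

1. **Intrinsic attributes** — 64-bit folded Morgan fingerprints for drugs
   (RDKit, radius 2) and 64-dim 3-mer composition over a 4-group reduced
   amino-acid alphabet for proteins.
2. **Local structure (GF)** — one untrained graph-convolution pass: the
   symmetrically normalized self-looped adjacency aggregates neighbor
   attributes through a random Glorot weight matrix and ReLU, then the raw
   attributes are concatenated back (128-dim by default).
3. **Global structure (ψ)** — DeepWalk: truncated uniform random walks plus
   a from-scratch skip-gram trainer (hierarchical softmax over a Huffman
   tree by default; negative sampling optional).

Drug–protein pairs are scored by concatenating the two endpoint
representations and classifying with a random forest (LR / KNN / GBDT also
registered) under stratified 5-fold cross-validation, with a strict
leakage policy (test edges removed before computing structural features)
or a full-graph alternative. A synthetic planted-partition fixture
generator makes every stage testable without any licensed dataset.

## CLI

```bash
# synthetic fixture: edges.tsv, drugs.smi, proteins.fasta, labels.tsv
lgdti synth --drugs 60 --proteins 40 --blocks 2 --p-in 0.3 --p-out 0.02 \
            --seed 0 --out-dir data/

# cross-validated evaluation (writes a JSON report with the full config)
lgdti cv --edges data/edges.tsv --smiles data/drugs.smi \
         --fasta data/proteins.fasta --mode lgdti --classifier rf \
         --folds 5 --seed 0 --leakage strict --out report.json

# rank unlinked candidate targets for one drug
lgdti rank --edges data/edges.tsv --smiles data/drugs.smi \
           --fasta data/proteins.fasta --drug D0000 --top 5

# node attribute matrix only
lgdti featurize --edges data/edges.tsv --smiles data/drugs.smi \
                --fasta data/proteins.fasta --out features.npz
```

Feature modes: `attribute` (X only), `gf` (GCN features), `lgdti`
(GF ⊕ ψ). One global `--seed` fans out to per-stage seeds; identical
config + seed reproduces reports byte-for-byte.

## Inputs

- edge list: two columns (drug_id, protein_id), tab/comma delimited,
  `#` comments, `--header/--no-header`;
- SMILES table: two columns (drug_id, smiles);
- protein FASTA keyed by record id.
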