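"""Pair-level classification: feature assembly, negative sampling,
cross-validated evaluation and candidate-target ranking.

Feature modes mirror the three node representations: ``attribute`` uses the
intrinsic attributes only, ``gf`` the GCN-aggregated local features, and
``lgdti`` concatenates the local features with the DeepWalk embeddings.
A pair's feature row is [drug block || protein block].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve, precision_recall_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .graph import BipartiteGraph, build_adjacency, normalize_adjacency
from .local import GCNWeights, gf_features, init_weights
from .embedding import WalkConfig, embed_nodes

logger = logging.getLogger(__name__)

FEATURE_MODES = ("attribute", "gf", "lgdti")
CLASSIFIERS = ("lr", "knn", "gbdt", "rf")


@dataclass(frozen=True)
class LabeledPairSet:
    """Drug-protein pairs with binary labels plus sampling provenance."""

    pairs: list[tuple[int, int, int]]  # (drug_index, protein_index, label)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = {(d, p) for d, p, _ in self.pairs}
        if len(seen) != len(self.pairs):
            raise ValueError("duplicate pair in labeled set")

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([lab for _, _, lab in self.pairs], dtype=np.int64)


@dataclass(frozen=True)
class GCNConfig:
    hidden_dim: int = 64
    n_layers: int = 1
    combine: str = "concat"
    seed: int = 0


def sample_negatives(
    g: BipartiteGraph, n_neg: int, seed: int
) -> list[tuple[int, int]]:
    """Uniform sample of n_neg distinct non-edges, reproducible per seed."""
    n, m = g.n_drugs, g.n_proteins
    n_non_edges = n * m - g.n_edges
    if n_neg > n_non_edges:
        raise ValueError(
            f"insufficient non-edges: requested {n_neg}, available {n_non_edges}"
        )
    is_edge = np.zeros((n, m), dtype=bool)
    for i, j in g.edges:
        is_edge[i, j] = True
    flat_non = np.flatnonzero(~is_edge.ravel())
    rng = np.random.default_rng(seed)
    chosen = rng.choice(flat_non, size=n_neg, replace=False)
    chosen.sort()
    return [(int(f) // m, int(f) % m) for f in chosen]


def make_pair_set(g: BipartiteGraph, ratio: float = 1.0, seed: int = 0) -> LabeledPairSet:
    """Positives are the graph's edges; negatives sampled 1:ratio from non-edges."""
    positives = [(i, j, 1) for i, j in g.sorted_edges()]
    n_neg = int(round(ratio * len(positives)))
    negatives = [(i, j, 0) for i, j in sample_negatives(g, n_neg, seed)]
    return LabeledPairSet(
        pairs=positives + negatives,
        provenance={"seed": seed, "ratio": ratio, "policy": "uniform-non-edges"},
    )


def node_representation(
    mode: str,
    x: np.ndarray | None,
    gf: np.ndarray | None,
    psi: np.ndarray | None,
) -> np.ndarray:
    if mode == "attribute":
        if x is None:
            raise ValueError("attribute mode requires x")
        return x
    if mode == "gf":
        if gf is None:
            raise ValueError("gf mode requires gf")
        return gf
    if mode == "lgdti":
        if gf is None or psi is None:
            raise ValueError("lgdti mode requires gf and psi")
        return np.hstack([gf, psi])
    raise ValueError(f"unknown feature mode: {mode!r}")


def pair_features(
    pairs: list[tuple[int, int, int]] | list[tuple[int, int]],
    mode: str,
    g: BipartiteGraph,
    x: np.ndarray | None = None,
    gf: np.ndarray | None = None,
    psi: np.ndarray | None = None,
) -> np.ndarray:
    """Feature table: one row [drug block || protein block] per pair."""
    rep = node_representation(mode, x, gf, psi)
    if rep.shape[0] != g.n_nodes:
        raise ValueError("representation does not cover all nodes")
    d_idx = np.asarray([p[0] for p in pairs], dtype=np.int64)
    p_idx = np.asarray([p[1] for p in pairs], dtype=np.int64)
    if len(d_idx) and (d_idx.max() >= g.n_drugs or p_idx.max() >= g.n_proteins):
        raise ValueError("pair index out of range")
    return np.hstack([rep[d_idx], rep[g.n_drugs + p_idx]])


def make_classifier(name: str, seed: int = 0):
    """Registry of classifiers at their library default parameters."""
    if name == "lr":
        return LogisticRegression(max_iter=1000, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier()
    if name == "gbdt":
        return GradientBoostingClassifier(random_state=seed)
    if name == "rf":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown classifier: {name!r}")


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5, curves: bool = False
) -> dict[str, Any]:
    """Threshold metrics plus AUROC (trapezoidal) and AUPR (step integral)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise ValueError("single-class labels: AUROC undefined")
    pred = (scores >= threshold).astype(np.int64)
    tp = float(np.sum((pred == 1) & (labels == 1)))
    tn = float(np.sum((pred == 0) & (labels == 0)))
    fp = float(np.sum((pred == 1) & (labels == 0)))
    fn = float(np.sum((pred == 0) & (labels == 1)))
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out: dict[str, Any] = {
        "acc": (tp + tn) / len(labels),
        "mcc": (tp * tn - fp * fn) / denom if denom > 0 else 0.0,
        "sen": tp / (tp + fn) if tp + fn > 0 else 0.0,
        "spec": tn / (tn + fp) if tn + fp > 0 else 0.0,
        "prec": tp / (tp + fp) if tp + fp > 0 else 0.0,
        "auroc": float(roc_auc_score(labels, scores)),
        "aupr": float(average_precision_score(labels, scores)),
    }
    if curves:
        fpr, tpr, _ = roc_curve(labels, scores)
        p, r, _ = precision_recall_curve(labels, scores)
        out["roc_curve"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist()}
        out["pr_curve"] = {"precision": p.tolist(), "recall": r.tolist()}
    return out


def _aggregate(folds: list[dict[str, Any]]) -> dict[str, Any]:
    keys = ("acc", "mcc", "sen", "spec", "prec", "auroc", "aupr")
    mean = {k: float(np.mean([f[k] for f in folds])) for k in keys}
    std = {k: float(np.std([f[k] for f in folds])) for k in keys}
    return {"folds": folds, "mean": mean, "std": std}


def _fit_and_score(
    features: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    classifier: str,
    seed: int,
    curves: bool = False,
) -> tuple[dict[str, Any], np.ndarray]:
    if len(np.unique(labels[test_idx])) < 2 or len(np.unique(labels[train_idx])) < 2:
        raise ValueError("degenerate fold; reduce k or add data")
    clf = make_classifier(classifier, seed)
    clf.fit(features[train_idx], labels[train_idx])
    scores = clf.predict_proba(features[test_idx])[:, 1]
    return compute_metrics(labels[test_idx], scores, curves=curves), scores


def _cv_core(
    features: np.ndarray,
    labels: np.ndarray,
    classifier: str = "rf",
    k: int = 5,
    seed: int = 0,
    curves: bool = False,
) -> dict[str, Any]:
    """k-fold CV on a fixed feature table (no per-fold graph recomputation)."""
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(features, labels):
        metrics, _ = _fit_and_score(
            features, labels, train_idx, test_idx, classifier, seed, curves
        )
        folds.append(metrics)
    return _aggregate(folds)


def _structural_features(
    g: BipartiteGraph,
    x: np.ndarray,
    mode: str,
    gcn_cfg: GCNConfig,
    walk_cfg: WalkConfig,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    gf = psi = None
    if mode in ("gf", "lgdti"):
        a_norm = normalize_adjacency(build_adjacency(g, add_self_loops=True))
        w = init_weights(x.shape[1], gcn_cfg.hidden_dim, gcn_cfg.seed)
        gf = gf_features(x, a_norm, w, n_layers=gcn_cfg.n_layers, mode=gcn_cfg.combine)
    if mode == "lgdti":
        psi = embed_nodes(g, walk_cfg).psi
    return gf, psi


def crossvalidate(
    pair_set: LabeledPairSet,
    g: BipartiteGraph,
    mode: str,
    x: np.ndarray,
    classifier: str = "rf",
    k: int = 5,
    seed: int = 0,
    leakage_policy: str = "strict",
    gcn_cfg: GCNConfig | None = None,
    walk_cfg: WalkConfig | None = None,
    curves: bool = False,
) -> dict[str, Any]:
    """Stratified k-fold evaluation of the pair classifier.

    Under ``leakage_policy="strict"`` the structural representations (GF and
    the walk embeddings) are recomputed per fold on the graph with that
    fold's positive test edges removed; ``"paper"`` computes them once on
    the full graph.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode: {mode!r}")
    if leakage_policy not in ("strict", "paper"):
        raise ValueError(f"unknown leakage policy: {leakage_policy!r}")
    gcn_cfg = gcn_cfg or GCNConfig()
    walk_cfg = walk_cfg or WalkConfig()

    pairs = pair_set.pairs
    labels = pair_set.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")

    if mode == "attribute" or leakage_policy == "paper":
        gf, psi = _structural_features(g, x, mode, gcn_cfg, walk_cfg)
        feats = pair_features(pairs, mode, g, x=x, gf=gf, psi=psi)
        return _cv_core(feats, labels, classifier, k, seed, curves)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_idx, test_idx in skf.split(np.zeros(len(pairs)), labels):
        held_out = {
            (pairs[i][0], pairs[i][1]) for i in test_idx if pairs[i][2] == 1
        }
        g_fold = g.remove_edges(held_out)
        gf, psi = _structural_features(g_fold, x, mode, gcn_cfg, walk_cfg)
        feats = pair_features(pairs, mode, g, x=x, gf=gf, psi=psi)
        metrics, _ = _fit_and_score(
            feats, labels, train_idx, test_idx, classifier, seed, curves
        )
        folds.append(metrics)
    return _aggregate(folds)


def train_full(
    pair_set: LabeledPairSet,
    g: BipartiteGraph,
    mode: str,
    x: np.ndarray,
    classifier: str = "rf",
    seed: int = 0,
    gcn_cfg: GCNConfig | None = None,
    walk_cfg: WalkConfig | None = None,
):
    """Fit the classifier on every labeled pair (for ranking new candidates)."""
    gcn_cfg = gcn_cfg or GCNConfig()
    walk_cfg = walk_cfg or WalkConfig()
    gf, psi = _structural_features(g, x, mode, gcn_cfg, walk_cfg)
    feats = pair_features(pair_set.pairs, mode, g, x=x, gf=gf, psi=psi)
    clf = make_classifier(classifier, seed)
    clf.fit(feats, pair_set.labels)
    return clf, {"x": x, "gf": gf, "psi": psi}


def rank_targets(
    drug_id: str,
    model,
    g: BipartiteGraph,
    mode: str,
    reps: dict[str, np.ndarray | None],
) -> list[tuple[str, float]]:
    """Score every protein not already linked to the drug, best first.

    Ties break by protein id so rankings are reproducible.
    """
    try:
        d = g.drug_ids.index(drug_id)
    except ValueError:
        raise ValueError(f"unknown drug id: {drug_id!r}") from None
    linked = {j for i, j in g.edges if i == d}
    candidates = [j for j in range(g.n_proteins) if j not in linked]
    if not candidates:
        return []
    feats = pair_features(
        [(d, j) for j in candidates], mode, g,
        x=reps.get("x"), gf=reps.get("gf"), psi=reps.get("psi"),
    )
    scores = model.predict_proba(feats)[:, 1]
    ranked = sorted(
        zip((g.protein_ids[j] for j in candidates), scores),
        key=lambda item: (-item[1], item[0]),
    )
    return [(pid, float(s)) for pid, s in ranked]
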