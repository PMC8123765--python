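import numpy as np
import pytest

from lgdti import (
    BipartiteGraph,
    PlantedPartitionSpec,
    WalkConfig,
    compute_metrics,
    crossvalidate,
    make_pair_set,
    pair_features,
    rank_targets,
    sample_negatives,
    synth_graph,
    train_full,
)
from lgdti.model import LabeledPairSet, _cv_core, make_classifier


def auroc_bruteforce(labels, scores):
    """Independent pairwise-comparison estimator of AUROC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestSampleNegatives:
    def test_complete_bipartite_has_no_non_edges(self):
        g = BipartiteGraph(("d1",), ("t1",), frozenset({(0, 0)}))
        with pytest.raises(ValueError, match="insufficient non-edges"):
            sample_negatives(g, 1, seed=0)

    def test_exhaustive_two_by_two(self):
        g = BipartiteGraph(
            ("d1", "d2"), ("t1", "t2"), frozenset({(0, 0), (1, 1)})
        )
        negs = sample_negatives(g, 2, seed=0)
        assert sorted(negs) == [(0, 1), (1, 0)]

    def test_seed_reproducibility(self):
        g, _, _ = synth_graph(PlantedPartitionSpec(10, 10, 2, 0.4, 0.05, seed=0))
        assert sample_negatives(g, 20, seed=3) == sample_negatives(g, 20, seed=3)

    def test_negatives_are_non_edges(self):
        g, _, _ = synth_graph(PlantedPartitionSpec(10, 10, 2, 0.4, 0.05, seed=1))
        for pair in sample_negatives(g, 30, seed=4):
            assert pair not in g.edges


class TestPairSet:
    def test_positives_are_exactly_edges(self):
        g, _, _ = synth_graph(PlantedPartitionSpec(8, 8, 2, 0.5, 0.05, seed=2))
        ps = make_pair_set(g, seed=0)
        pos = {(d, p) for d, p, lab in ps.pairs if lab == 1}
        assert pos == set(g.edges)
        neg = [(d, p) for d, p, lab in ps.pairs if lab == 0]
        assert len(neg) == g.n_edges

    def test_duplicate_pairs_rejected(self):
        with pytest.raises(ValueError, match="duplicate pair"):
            LabeledPairSet(pairs=[(0, 0, 1), (0, 0, 0)])


class TestPairFeatures:
    def setup_method(self):
        self.g = BipartiteGraph(("d1", "d2"), ("t1",), frozenset({(0, 0)}))
        rng = np.random.default_rng(0)
        self.x = rng.random((3, 64))
        self.gf = rng.random((3, 128))
        self.psi = rng.random((3, 64))

    def test_attribute_width(self):
        feats = pair_features([(0, 0)], "attribute", self.g, x=self.x)
        assert feats.shape == (1, 128)

    def test_gf_width(self):
        feats = pair_features([(0, 0)], "gf", self.g, gf=self.gf)
        assert feats.shape == (1, 256)

    def test_lgdti_width(self):
        feats = pair_features(
            [(0, 0)], "lgdti", self.g, gf=self.gf, psi=self.psi
        )
        assert feats.shape == (1, 384)

    def test_row_is_elementwise_concatenation(self):
        feats = pair_features([(1, 0)], "lgdti", self.g, gf=self.gf, psi=self.psi)
        drug_block = np.concatenate([self.gf[1], self.psi[1]])
        prot_block = np.concatenate([self.gf[2], self.psi[2]])
        np.testing.assert_array_equal(feats[0], np.concatenate([drug_block, prot_block]))

    def test_out_of_range_pair(self):
        with pytest.raises(ValueError, match="out of range"):
            pair_features([(5, 0)], "attribute", self.g, x=self.x)


class TestComputeMetrics:
    def test_perfect_confusion(self):
        labels = np.array([1] * 5 + [0] * 5)
        scores = labels.astype(float)
        m = compute_metrics(labels, scores)
        for key in ("acc", "mcc", "sen", "spec", "prec", "auroc", "aupr"):
            assert m[key] == pytest.approx(1.0)

    def test_hand_confusion_matrix(self):
        # TP=3, FN=2, FP=1, TN=2 at threshold 0.5
        labels = np.array([1, 1, 1, 1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.9, 0.9, 0.1, 0.1, 0.9, 0.1, 0.1])
        m = compute_metrics(labels, scores)
        assert m["mcc"] == pytest.approx(4 / np.sqrt(240))
        assert m["acc"] == pytest.approx(0.625)
        assert m["sen"] == pytest.approx(0.6)
        assert m["spec"] == pytest.approx(2 / 3)
        assert m["prec"] == pytest.approx(0.75)

    def test_auroc_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # ties occur
            m = compute_metrics(labels, scores)
            assert m["auroc"] == pytest.approx(
                auroc_bruteforce(labels, scores), abs=1e-9
            )

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="single-class"):
            compute_metrics(np.ones(4), np.random.default_rng(0).random(4))

    def test_curve_points_returned(self):
        labels = np.array([0, 1, 0, 1])
        m = compute_metrics(labels, np.array([0.1, 0.9, 0.4, 0.6]), curves=True)
        assert m["roc_curve"]["fpr"][0] == 0.0
        assert len(m["pr_curve"]["precision"]) == len(m["pr_curve"]["recall"])


class TestCrossValidate:
    def test_leaking_feature_hits_ceiling(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, size=400)
        feats = rng.random((400, 10))
        feats[:, 0] = labels  # label leaks into a column
        rep = _cv_core(feats, labels, classifier="rf", k=5, seed=0)
        assert rep["mean"]["acc"] == pytest.approx(1.0)
        assert rep["mean"]["mcc"] == pytest.approx(1.0)
        assert rep["mean"]["auroc"] == pytest.approx(1.0)

    def test_null_features_near_chance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=600)
        feats = rng.random((600, 16))
        rep = _cv_core(feats, labels, classifier="rf", k=5, seed=1)
        assert abs(rep["mean"]["auroc"] - 0.5) < 0.07

    def test_partition_contract(self, planted_dataset):
        from sklearn.model_selection import StratifiedKFold

        ps = planted_dataset["pairs"]
        labels = ps.labels
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = np.zeros(len(labels), dtype=int)
        for _, test_idx in skf.split(np.zeros(len(labels)), labels):
            seen[test_idx] += 1
        np.testing.assert_array_equal(seen, 1)

    def test_stratification_within_two_percent(self, planted_dataset):
        from sklearn.model_selection import StratifiedKFold

        labels = planted_dataset["pairs"].labels
        global_frac = labels.mean()
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, test_idx in skf.split(np.zeros(len(labels)), labels):
            assert abs(labels[test_idx].mean() - global_frac) <= 0.02

    def test_attribute_mode_runs(self, planted_dataset):
        rep = crossvalidate(
            planted_dataset["pairs"],
            planted_dataset["graph"],
            "attribute",
            planted_dataset["x"],
            k=5,
            seed=0,
        )
        assert set(rep) == {"folds", "mean", "std"}
        assert len(rep["folds"]) == 5
        assert 0 <= rep["mean"]["auroc"] <= 1

    def test_strict_leakage_recomputes_per_fold(self, planted_dataset):
        wcfg = WalkConfig(walk_length=10, window=3, epochs=2, dim=8, seed=0)
        strict = crossvalidate(
            planted_dataset["pairs"], planted_dataset["graph"], "lgdti",
            planted_dataset["x"], k=3, seed=0, leakage_policy="strict",
            walk_cfg=wcfg,
        )
        paper = crossvalidate(
            planted_dataset["pairs"], planted_dataset["graph"], "lgdti",
            planted_dataset["x"], k=3, seed=0, leakage_policy="paper",
            walk_cfg=wcfg,
        )
        assert strict["mean"]["auroc"] != paper["mean"]["auroc"]

    def test_reproducibility(self, planted_dataset):
        kwargs = dict(
            mode="gf", x=planted_dataset["x"], classifier="rf", k=3, seed=7
        )
        r1 = crossvalidate(planted_dataset["pairs"], planted_dataset["graph"], **kwargs)
        r2 = crossvalidate(planted_dataset["pairs"], planted_dataset["graph"], **kwargs)
        assert r1 == r2

    def test_degenerate_fold_raises(self):
        g = BipartiteGraph(
            ("d1", "d2"), ("t1", "t2"), frozenset({(0, 0), (1, 1)})
        )
        ps = make_pair_set(g, seed=0)
        x = np.random.default_rng(0).random((4, 8))
        with pytest.raises(ValueError):
            crossvalidate(ps, g, "attribute", x, k=4, seed=0)

    @pytest.mark.parametrize("name", ["lr", "knn", "gbdt", "rf"])
    def test_classifier_registry(self, name):
        clf = make_classifier(name, seed=0)
        assert hasattr(clf, "fit")

    def test_unknown_classifier(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            make_classifier("svm")


class TestRankTargets:
    def _trained(self, planted_dataset, mode="gf"):
        return train_full(
            planted_dataset["pairs"], planted_dataset["graph"], mode,
            planted_dataset["x"], seed=0,
        )

    def test_fully_linked_drug_returns_empty(self):
        g = BipartiteGraph(("d1",), ("t1", "t2"), frozenset({(0, 0), (0, 1)}))
        rng = np.random.default_rng(0)
        x = rng.random((3, 8))
        ps = LabeledPairSet(pairs=[(0, 0, 1), (0, 1, 0)])
        clf, reps = train_full(ps, g, "attribute", x, seed=0)
        assert rank_targets("d1", clf, g, "attribute", reps) == []

    def test_scores_non_increasing_and_excludes_linked(self, planted_dataset):
        g = planted_dataset["graph"]
        clf, reps = self._trained(planted_dataset)
        drug = g.drug_ids[0]
        ranked = rank_targets(drug, clf, g, "gf", reps)
        scores = [s for _, s in ranked]
        assert scores == sorted(scores, reverse=True)
        linked = {g.protein_ids[j] for i, j in g.edges if i == 0}
        assert not linked & {pid for pid, _ in ranked}
        assert len(ranked) == g.n_proteins - len(linked)

    def test_unknown_drug_raises(self, planted_dataset):
        clf, reps = self._trained(planted_dataset)
        with pytest.raises(ValueError, match="unknown drug"):
            rank_targets("nope", clf, planted_dataset["graph"], "gf", reps)

    def test_planted_block_recovery(self):
        # a drug's top-5 candidates should mostly share its block
        hits = []
        wcfg_base = dict(walk_length=15, window=3, epochs=4, dim=16)
        for seed in range(5):
            g, db, pb = synth_graph(
                PlantedPartitionSpec(30, 20, 2, 0.5, 0.03, seed=seed)
            )
            rng = np.random.default_rng(seed)
            x = rng.random((g.n_nodes, 16))
            ps = make_pair_set(g, seed=seed)
            wcfg = WalkConfig(seed=seed + 30, **wcfg_base)
            clf, reps = train_full(ps, g, "lgdti", x, seed=seed, walk_cfg=wcfg)
            drug = g.drug_ids[0]
            top5 = rank_targets(drug, clf, g, "lgdti", reps)[:5]
            block = db[0]
            pid_block = {g.protein_ids[j]: pb[j] for j in range(g.n_proteins)}
            hits.append(sum(pid_block[pid] == block for pid, _ in top5))
        assert np.mean(hits) >= 3


class TestFeatureModeOrdering:
    def test_lgdti_geq_gf_geq_attribute(self):
        res = {"attribute": [], "gf": [], "lgdti": []}
        wcfg_base = dict(walk_length=15, window=3, epochs=4, dim=16)
        for seed in range(3):
            g, _, _ = synth_graph(
                PlantedPartitionSpec(40, 30, 2, 0.35, 0.03, seed=seed)
            )
            x = np.random.default_rng(seed).random((g.n_nodes, 32))
            ps = make_pair_set(g, seed=seed + 1)
            wcfg = WalkConfig(seed=seed + 60, **wcfg_base)
            for mode in res:
                rep = crossvalidate(
                    ps, g, mode, x, k=3, seed=seed + 2,
                    leakage_policy="paper", walk_cfg=wcfg,
                )
                res[mode].append(rep["mean"]["auroc"])
        means = {m: np.mean(v) for m, v in res.items()}
        assert means["lgdti"] >= means["gf"] >= means["attribute"]
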