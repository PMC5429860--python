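import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from neuroconsensus.classifier_eval import (
    LabeledDataset,
    assemble_negative_set,
    assemble_positive_set,
    build_feature_vectors,
    cross_validate,
    evaluate_predictions,
    rank_candidates,
    roc_auc,
    stratified_split,
    train_test_evaluate,
)


def _evidence_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "evidence_category"])


def _tissue_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "specificity_category"])


def separable_dataset(n_pos=20, n_neg=40, n_feat=6, seed=0, gap=5.0):
    rng = np.random.default_rng(seed)
    Xp = rng.normal(size=(n_pos, n_feat)) + gap
    Xn = rng.normal(size=(n_neg, n_feat))
    X = pd.DataFrame(np.vstack([Xp, Xn]),
                     index=[f"g{i}" for i in range(n_pos + n_neg)],
                     columns=[f"S{j}" for j in range(n_feat)])
    y = pd.Series([1] * n_pos + [0] * n_neg, index=X.index)
    return LabeledDataset(X, y)


class TestGeneSetAssembly:
    def test_keep_filter(self):
        t = _evidence_table([("a", "syndromic"), ("b", "syndromic"),
                             ("c", "replicated"), ("d", "minimal"),
                             ("e", "minimal")])
        assert assemble_positive_set(t) == {"a", "b", "c"}
        all_cats = {"syndromic", "replicated", "minimal", "hypothesized"}
        assert assemble_positive_set(t, keep=all_cats) == {"a", "b", "c", "d", "e"}

    def test_unknown_category_raises(self):
        with pytest.raises(ValueError, match="unknown evidence"):
            assemble_positive_set(_evidence_table([("a", "mystery")]))

    def test_evidence_funnel_matches_filter_loop(self):
        rng = np.random.default_rng(81)
        cats = ["syndromic", "replicated", "minimal", "hypothesized"]
        rows = [(f"g{i}", cats[rng.integers(4)]) for i in range(845)]
        t = _evidence_table(rows)
        got = assemble_positive_set(t)
        expected = {g for g, c in rows if c in ("syndromic", "replicated")}
        assert got == expected

    def test_negative_set_algebra(self):
        t = _tissue_table([(f"e{i}", "elevated") for i in range(10)]
                          + [("ge1", "group_enriched"), ("ge2", "group_enriched")])
        out = assemble_negative_set(t, positives={"e9"})
        assert out == {f"e{i}" for i in range(9)}

    def test_negative_set_randomized_matches_oracle(self):
        rng = np.random.default_rng(82)
        genes = [f"g{i}" for i in range(200)]
        cats = rng.choice(["elevated", "group_enriched", "not_elevated"], size=200)
        t = _tissue_table(list(zip(genes, cats)))
        positives = set(rng.choice(genes, size=30, replace=False))
        got = assemble_negative_set(t, positives)
        A = {g for g, c in zip(genes, cats) if c == "elevated"}
        B = {g for g, c in zip(genes, cats) if c == "group_enriched"}
        assert got == A - B - positives


class TestFeatureVectors:
    def test_join_shape_and_imputation(self, caplog):
        expr = pd.DataFrame(np.arange(32.0).reshape(8, 4),
                            index=[f"g{i}" for i in range(8)],
                            columns=[f"S{j}" for j in range(4)])
        expr.iloc[0, 0] = np.nan
        d = build_feature_vectors({f"g{i}" for i in range(3)},
                                  {f"g{i}" for i in range(3, 8)}, expr)
        assert d.X.shape == (8, 4)
        assert d.n_pos == 3 and d.n_neg == 5
        assert d.X.iloc[0, 0] == 0.0  # imputed on the z scale

    def test_absent_gene_dropped_and_class_loss_raises(self):
        expr = pd.DataFrame(np.ones((2, 2)), index=["g0", "g1"],
                            columns=["S0", "S1"])
        d = build_feature_vectors({"g0", "missing"}, {"g1"}, expr)
        assert list(d.y.index) == ["g0", "g1"]
        with pytest.raises(ValueError, match="lost all"):
            build_feature_vectors({"missing"}, {"g1"}, expr)

    def test_overlapping_classes_raise(self):
        expr = pd.DataFrame(np.ones((2, 2)), index=["g0", "g1"],
                            columns=["S0", "S1"])
        with pytest.raises(ValueError, match="both classes"):
            build_feature_vectors({"g0"}, {"g0", "g1"}, expr)


class TestStratifiedSplit:
    def test_exact_ratios_small(self):
        d = separable_dataset(n_pos=10, n_neg=40)
        split = stratified_split(d, 0.8, seed=0)
        y = d.y
        tr = y.loc[split.train_genes]
        te = y.loc[split.test_genes]
        assert ((tr == 1).sum(), (tr == 0).sum()) == (8, 32)
        assert ((te == 1).sum(), (te == 0).sum()) == (2, 8)

    def test_study_scale_rounding(self):
        """219 positives / 830 negatives at 0.8 -> train 175/664, test 44/166
        by per-class rounding to nearest."""
        d = separable_dataset(n_pos=219, n_neg=830, n_feat=3)
        split = stratified_split(d, 0.8, seed=3)
        tr = d.y.loc[split.train_genes]
        te = d.y.loc[split.test_genes]
        assert ((tr == 1).sum(), (tr == 0).sum()) == (175, 664)
        assert ((te == 1).sum(), (te == 0).sum()) == (44, 166)

    def test_deterministic_and_disjoint(self):
        d = separable_dataset()
        s1 = stratified_split(d, seed=11)
        s2 = stratified_split(d, seed=11)
        assert s1.train_genes == s2.train_genes and s1.test_genes == s2.test_genes
        assert not set(s1.train_genes) & set(s1.test_genes)
        assert set(s1.train_genes) | set(s1.test_genes) == set(d.y.index)

    def test_tiny_class_raises(self):
        d = separable_dataset(n_pos=1, n_neg=10)
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_split(d)


class TestRocAuc:
    def test_perfect_separation(self):
        _, _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_hand_enumerated_pairs(self):
        # positives 0.9, 0.1 vs negatives 0.8, 0.2: pairs (0.9,0.8) and
        # (0.9,0.2) concordant, (0.1,0.8) and (0.1,0.2) discordant -> 0.5
        _, _, auc = roc_auc([0.9, 0.1, 0.8, 0.2], [1, 1, 0, 0])
        assert auc == pytest.approx(0.5)
        # positives 0.9, 0.2 vs negatives 0.8, 0.1: 3 of 4 pairs concordant
        _, _, auc = roc_auc([0.9, 0.2, 0.8, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(0.75)

    def test_equals_mann_whitney_with_ties(self):
        rng = np.random.default_rng(83)
        for _ in range(20):
            n = 30
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            _, _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(oracle.mann_whitney_auc(scores, labels),
                                        abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(84)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        _, _, a1 = roc_auc(scores, labels)
        _, _, a2 = roc_auc(np.exp(3 * scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_roc_curve_shape(self):
        fpr, tpr, _ = roc_auc([0.9, 0.4, 0.6, 0.1], [1, 0, 1, 0])
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()

    def test_constant_scores_chance(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            _, _, auc = roc_auc([0.5, 0.5, 0.5], [1, 0, 1])
        assert auc == 0.5
        assert "constant" in caplog.text


class TestMetrics:
    def test_identities_hold(self):
        rng = np.random.default_rng(85)
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        scores = rng.random(100)
        r = evaluate_predictions(labels, scores)
        c = r.confusion
        n = sum(c.values())
        assert r.accuracy == pytest.approx((c["tp"] + c["tn"]) / n)
        assert r.fpr + r.tnr == pytest.approx(1.0)
        if r.precision + r.tpr > 0:
            assert r.f1 == pytest.approx(
                2 * r.precision * r.tpr / (r.precision + r.tpr))
        for k in ("accuracy", "tpr", "fpr", "tnr", "fnr", "precision", "f1", "auc"):
            assert 0.0 <= getattr(r, k) <= 1.0


class TestCrossValidate:
    def test_separable_data_perfect_accuracy(self):
        d = separable_dataset(n_pos=20, n_neg=40, seed=1)
        report = cross_validate(d, k=10, seed=0)
        assert report.accuracy == 1.0
        assert report.auc == 1.0
        assert len(report.per_fold) == 10

    def test_each_gene_tested_exactly_once(self):
        from sklearn.model_selection import StratifiedKFold

        d = separable_dataset(n_pos=15, n_neg=25)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        seen = []
        for _, te in skf.split(d.X, d.y):
            seen.extend(te)
        assert sorted(seen) == list(range(len(d.y)))

    def test_class_too_small_raises(self):
        d = separable_dataset(n_pos=5, n_neg=40)
        with pytest.raises(ValueError, match="k=10"):
            cross_validate(d, k=10)

    def test_fold_stratification_within_one(self):
        from sklearn.model_selection import StratifiedKFold

        d = separable_dataset(n_pos=21, n_neg=39)
        ratio = d.n_pos / len(d.y)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=0)
        y = d.y.to_numpy()
        for _, te in skf.split(d.X, y):
            n_pos = y[te].sum()
            assert abs(n_pos - ratio * len(te)) <= 1


class TestHeldOutAndRanking:
    def test_train_test_separable(self):
        d = separable_dataset(n_pos=20, n_neg=40, seed=2)
        split = stratified_split(d, seed=5)
        report = train_test_evaluate(d, split, seed=5)
        assert report.accuracy == 1.0

    def test_candidate_ranking_prefers_positive_like_profiles(self):
        d = separable_dataset(n_pos=20, n_neg=40, seed=3, gap=5.0)
        rng = np.random.default_rng(86)
        pos_like = rng.normal(size=(3, 6)) + 5.0
        neg_like = rng.normal(size=(3, 6))
        cand = pd.DataFrame(np.vstack([pos_like, neg_like]),
                            index=[f"c{i}" for i in range(6)],
                            columns=d.X.columns)
        ranked = rank_candidates(d, cand, seed=0)
        assert set(ranked.index[:3]) == {"c0", "c1", "c2"}
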