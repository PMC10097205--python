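import numpy as np
import pandas as pd
import pytest

from lspsuite.datasets import SCHEMES, LabeledDataset
from lspsuite.features import FeatureTable, extract_features
from lspsuite.sequence_io import ProteinRecord
from lspsuite.training import (
    BalancedRandomForest,
    CVResult,
    FoldResult,
    ModelBundle,
    balanced_accuracy,
    cross_validate,
    estimate_bias,
    select_top_features,
    stratified_split,
    threshold_at_fpr,
    _fold_threshold,
)


def toy_dataset(n_pos=8, n_neg=80, seed=0, separation=3.0):
    """Two-feature Gaussian toy data wrapped as a LabeledDataset."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(separation, 1.0, size=(n_pos, 2)),
            rng.normal(0.0, 1.0, size=(n_neg, 2)),
        ]
    )
    y = np.array([1] * n_pos + [0] * n_neg)
    ids = [f"p{i}" for i in range(len(y))]
    frame = pd.DataFrame(X, index=ids, columns=["f1", "f2"])
    return LabeledDataset(
        scheme=SCHEMES["LSPpred1"],
        records=[ProteinRecord(i, "MKV") for i in ids],
        labels=y,
        feature_table=FeatureTable(frame),
    )


class TestBalancedRandomForest:
    def test_separable_training_accuracy(self):
        ds = toy_dataset(separation=6.0)
        model = BalancedRandomForest(n_estimators=50, random_state=0)
        model.fit(ds.feature_table.values, ds.labels)
        predictions = (model.score_samples(ds.feature_table.values) >= 0.5).astype(int)
        assert (predictions == ds.labels).all()

    def test_per_tree_bootstraps_are_balanced(self):
        ds = toy_dataset(n_pos=4, n_neg=200)
        model = BalancedRandomForest(n_estimators=20, random_state=0)
        model.fit(ds.feature_table.values, ds.labels)
        assert all(a == b == 4 for a, b in model._bootstrap_counts)

    def test_single_class_input_rejected(self):
        model = BalancedRandomForest(n_estimators=5)
        with pytest.raises(ValueError):
            model.fit(np.zeros((10, 2)), np.zeros(10, dtype=int))

    def test_probabilities_bounded_and_importances_normalised(self):
        ds = toy_dataset()
        model = BalancedRandomForest(n_estimators=30, random_state=1)
        model.fit(ds.feature_table.values, ds.labels)
        scores = model.score_samples(ds.feature_table.values)
        assert (scores >= 0).all() and (scores <= 1).all()
        assert model.feature_importances_.sum() == pytest.approx(1.0)

    def test_label_shuffled_null_auroc_near_half(self):
        ds = toy_dataset(n_pos=30, n_neg=120, separation=2.5, seed=4)
        rng = np.random.default_rng(7)
        shuffled = rng.permutation(ds.labels)
        cv = cross_validate(
            ds.feature_table.values, shuffled, ["f1", "f2"],
            n_folds=5, seed=7, n_estimators=60,
        )
        assert 0.4 <= cv.auroc_mean <= 0.6


class TestStratifiedSplit:
    def test_proportions(self):
        ds = toy_dataset(n_pos=8, n_neg=80)
        train, test = stratified_split(ds, 0.25, seed=0)
        y = ds.labels
        assert y[test].sum() == 2 and len(test) == 22
        assert y[train].sum() == 6 and len(train) == 66

    def test_partition_and_determinism(self):
        ds = toy_dataset()
        a_train, a_test = stratified_split(ds, 0.25, seed=3)
        b_train, b_test = stratified_split(ds, 0.25, seed=3)
        assert np.array_equal(a_train, b_train) and np.array_equal(a_test, b_test)
        union = np.sort(np.concatenate([a_train, a_test]))
        assert np.array_equal(union, np.arange(len(ds.labels)))

    def test_tiny_class_error(self):
        ds = toy_dataset(n_pos=1, n_neg=10)
        with pytest.raises(ValueError):
            stratified_split(ds, 0.25, seed=0)


class TestCrossValidate:
    def test_each_sample_scored_once_and_auroc_bounds(self):
        ds = toy_dataset(n_pos=15, n_neg=60)
        cv = cross_validate(
            ds.feature_table.values, ds.labels, ["f1", "f2"],
            n_folds=5, seed=0, n_estimators=40,
        )
        assert cv.n_folds == 5
        assert sum(len(f.scores) for f in cv.folds) == len(ds.labels)
        for fold in cv.folds:
            assert 0.0 <= fold.auroc <= 1.0
            assert np.all(np.diff(fold.fpr) >= 0)  # ROC points monotone

    def test_separable_data_high_auroc(self):
        ds = toy_dataset(n_pos=15, n_neg=60, separation=5.0)
        cv = cross_validate(
            ds.feature_table.values, ds.labels, ["f1", "f2"],
            n_folds=5, seed=0, n_estimators=40,
        )
        assert cv.auroc_mean > 0.95

    def test_too_few_positives_suggests_fewer_folds(self):
        ds = toy_dataset(n_pos=3, n_neg=30)
        with pytest.raises(ValueError, match="n_folds"):
            cross_validate(ds.feature_table.values, ds.labels, ["f1", "f2"], n_folds=5)


def brute_force_threshold(scores, labels, target):
    """Enumerate every candidate cutoff; max TPR s.t. FPR <= target."""
    negatives = scores[labels == 0]
    positives = scores[labels == 1]
    candidates = np.concatenate([np.unique(scores), [scores.max() + 1.0]])
    feasible = []
    for threshold in candidates:
        fpr = np.mean(negatives >= threshold) if negatives.size else 0.0
        tpr = np.mean(positives >= threshold) if positives.size else 0.0
        if fpr <= target:
            feasible.append((tpr, -threshold))
    best_tpr, negated = max(feasible)
    return -negated, best_tpr


class TestThresholdAtFpr:
    def test_twenty_negatives_allows_one_false_positive(self):
        rng = np.random.default_rng(0)
        negatives = np.sort(rng.uniform(0, 0.8, 20))
        positives = rng.uniform(0.5, 1.0, 10)
        scores = np.concatenate([negatives, positives])
        labels = np.array([0] * 20 + [1] * 10)
        threshold, _ = _fold_threshold(scores, labels, 0.05)
        # FPR <= 0.05 permits exactly one of 20 negatives at/above threshold
        assert np.sum(negatives >= threshold) <= 1
        oracle_threshold, oracle_tpr = brute_force_threshold(scores, labels, 0.05)
        assert threshold == pytest.approx(oracle_threshold)

    def test_identical_folds_mean_is_common_value(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        folds = [
            FoldResult(scores=scores, labels=labels, fpr=np.array([]),
                       tpr=np.array([]), roc_thresholds=np.array([]), auroc=1.0)
            for _ in range(5)
        ]
        cv = CVResult(folds=folds, feature_names=["f"])
        threshold, tpr = threshold_at_fpr(cv, 0.05)
        assert threshold == pytest.approx(0.8) and tpr == 1.0

    def test_perfect_separation_tpr_one_at_fpr_zero(self):
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        labels = np.array([0, 0, 0, 1, 1, 1])
        threshold, tpr = _fold_threshold(scores, labels, 0.0)
        assert tpr == 1.0
        assert np.mean(scores[labels == 0] >= threshold) == 0.0

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_neg = int(rng.integers(5, 40))
            n_pos = int(rng.integers(3, 20))
            scores = np.round(rng.random(n_neg + n_pos), 3)  # force ties
            labels = np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)])
            target = float(rng.choice([0.0, 0.05, 0.1, 0.25]))
            threshold, tpr = _fold_threshold(scores, labels, target)
            oracle_threshold, oracle_tpr = brute_force_threshold(
                scores, labels, target
            )
            assert tpr == pytest.approx(oracle_tpr)
            fpr = np.mean(scores[labels == 0] >= threshold)
            assert fpr <= target + 1e-12


class TestSelectTopFeatures:
    @staticmethod
    def cv_with_importances(importances):
        names = [f"f{i}" for i in range(len(importances))]
        fold = FoldResult(
            scores=np.array([]), labels=np.array([]), fpr=np.array([]),
            tpr=np.array([]), roc_thresholds=np.array([]), auroc=0.5,
            importances=np.asarray(importances, dtype=float),
        )
        return CVResult(folds=[fold], feature_names=names)

    def test_quarter_of_hundred_distinct(self):
        rng = np.random.default_rng(0)
        cv = self.cv_with_importances(rng.permutation(100).astype(float))
        assert len(select_top_features(cv)) == 25

    def test_all_equal_importances_keeps_everything(self):
        cv = self.cv_with_importances(np.ones(40))
        assert len(select_top_features(cv)) == 40

    def test_invariant_to_feature_permutation(self):
        rng = np.random.default_rng(1)
        importances = rng.random(60)
        cv = self.cv_with_importances(importances)
        kept = set(select_top_features(cv))
        order = rng.permutation(60)
        permuted_cv = CVResult(
            folds=[FoldResult(
                scores=np.array([]), labels=np.array([]), fpr=np.array([]),
                tpr=np.array([]), roc_thresholds=np.array([]), auroc=0.5,
                importances=importances[order],
            )],
            feature_names=[f"f{i}" for i in order],
        )
        assert set(select_top_features(permuted_cv)) == kept


class TestBalancedAccuracy:
    @pytest.mark.parametrize(
        "tp,fn,tn,fp,expected",
        [
            (8, 2, 6, 4, 0.7),   # pos acc 0.8, neg acc 0.6
            (10, 0, 10, 0, 1.0),
            (0, 10, 10, 0, 0.5),  # no positives predicted
            (5, 5, 5, 5, 0.5),
        ],
    )
    def test_closed_form_on_confusion_tables(self, tp, fn, tn, fp, expected):
        y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
        y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(expected)


class TestModelBundle:
    def test_save_load_round_trip(self, trained_pipeline, tmp_path):
        bundle, _, _ = trained_pipeline
        bundle.save(tmp_path / "bundle")
        loaded = ModelBundle.load(tmp_path / "bundle")
        assert loaded.threshold_high == bundle.threshold_high
        assert loaded.retained_features == bundle.retained_features
        records = [ProteinRecord("q", "MKVDEFILWWGGARNDQ" * 5)]
        assert np.allclose(bundle.score_records(records),
                           loaded.score_records(records))

    def test_out_of_fold_fpr_within_target_per_fold(self, trained_pipeline):
        _, _, cv = trained_pipeline
        for fold in cv.folds:
            negatives = fold.scores[fold.labels == 0]
            fpr = np.mean(negatives >= fold.threshold)
            assert fpr <= 0.05 + 1e-12


class TestEstimateBias:
    def test_identical_pairs_zero_and_antisymmetry(self, trained_pipeline):
        bundle, _, _ = trained_pipeline
        rng = np.random.default_rng(0)
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        originals = [
            ProteinRecord(f"p{i}", "".join(rng.choice(residues, 80)))
            for i in range(5)
        ]
        clipped = [
            ProteinRecord(r.id, r.sequence[20:], gene_id=r.gene_id)
            for r in originals
        ]
        same = estimate_bias(bundle, originals, originals)
        assert same.mean_difference == pytest.approx(0.0)
        forward = estimate_bias(bundle, clipped, originals)
        backward = estimate_bias(bundle, originals, clipped)
        assert forward.mean_difference == pytest.approx(-backward.mean_difference)

    def test_modification_trained_model_shows_larger_bias(self):
        """A model trained entirely on unmodified data barely shifts its
        scores when sequences lose an N-terminal prefix, whereas a model
        trained on prefix-removed positives keys on modification artefacts
        (missing initiator methionine) and shifts strongly."""
        from lspsuite.datasets import remove_prefix
        from lspsuite.features import extract_features
        from lspsuite.synth import SynthConfig, sample_background, sample_lsp_like
        from lspsuite.training import run_training_pipeline

        config = SynthConfig()
        rng = np.random.default_rng(21)
        positives = sample_lsp_like(40, config, rng, prefix="POS")
        negatives = sample_background(200, config, rng, prefix="NEG")
        clipped_positives = [remove_prefix(r, 20) for r in positives]

        def build(pos):
            records = pos + negatives
            labels = np.array([1] * len(pos) + [0] * len(negatives))
            return LabeledDataset(
                scheme=SCHEMES["LSPpred1"], records=records, labels=labels,
                feature_table=extract_features(records, scale=True),
            )

        unmodified_model, _, _ = run_training_pipeline(
            build(positives), seed=21, n_estimators=200
        )
        modified_model, _, _ = run_training_pipeline(
            build(clipped_positives), seed=21, n_estimators=200
        )
        eval_intact = sample_lsp_like(15, config, rng, prefix="EVA")
        eval_intact += sample_background(15, config, rng, prefix="EVB")
        eval_clipped = [remove_prefix(r, 20) for r in eval_intact]
        baseline = estimate_bias(unmodified_model, eval_clipped, eval_intact)
        inflated = estimate_bias(modified_model, eval_clipped, eval_intact)
        assert abs(inflated.mean_difference) > abs(baseline.mean_difference)

    def test_unmatched_ids_error(self, trained_pipeline):
        bundle, _, _ = trained_pipeline
        a = [ProteinRecord("x", "MKVDEF" * 10)]
        b = [ProteinRecord("y", "MKVDEF" * 10)]
        with pytest.raises(ValueError, match="unmatched"):
            estimate_bias(bundle, a, b)
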