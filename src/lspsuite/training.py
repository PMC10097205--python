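"""Balanced random-forest training with FPR-calibrated decision thresholds.

The classifier is an ensemble of randomised decision trees in which every
tree is fit on a class-balanced bootstrap: the minority-class count ``m``
is sampled with replacement from each class, so trees never see the raw
class imbalance.  Training proceeds as:

1. stratified 75/25 train/test split;
2. stratified 5-fold cross-validation on the training part, recording
   out-of-fold scores, per-fold ROC curves and Gini feature importances;
3. per fold, the smallest score threshold whose fold FPR does not exceed
   the target (default 0.05) is selected — this maximises TPR subject to
   the FPR bound — and the mean over folds gives the operating threshold
   and its TPR estimate;
4. features are ranked by mean importance and the upper quartile retained;
5. the ensemble is refit on the full training part restricted to the
   retained features, and balanced accuracy is reported on the held-out
   test part at the calibrated threshold and at 0.5.

Score bias introduced by sequence modification (signal-peptide removal
schemes) is estimated by scoring matched modified/unmodified record pairs
and summarising the per-protein score differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from lspsuite.datasets import LabeledDataset
from lspsuite.features import (
    DEFAULT_REGISTRY,
    FeatureRegistry,
    FeatureTable,
    extract_features,
)
from lspsuite.sequence_io import ProteinRecord

DEFAULT_FPR_TARGET = 0.05
DEFAULT_N_TREES = 500


class BalancedRandomForest:
    """Random forest over class-balanced bootstraps for imbalanced data.

    Each of ``n_estimators`` trees draws, with replacement, ``m`` samples
    from each class where ``m`` is the minority-class count, then fits an
    unpruned decision tree with sqrt-feature sampling per split.  Class
    probabilities are the mean of per-tree probabilities; feature
    importances are mean per-tree Gini importances (summing to 1).
    """

    def __init__(
        self,
        n_estimators: int = DEFAULT_N_TREES,
        max_features: str | int | float = "sqrt",
        max_depth: int | None = None,
        random_state: int | None = None,
    ) -> None:
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.max_depth = max_depth
        self.random_state = random_state
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_ = np.array([0, 1])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BalancedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        class_indices = [np.flatnonzero(y == c) for c in (0, 1)]
        if any(len(idx) == 0 for idx in class_indices):
            raise ValueError("both classes must be present in training data")
        m = min(len(idx) for idx in class_indices)
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        self._bootstrap_counts: list[tuple[int, int]] = []
        for _ in range(self.n_estimators):
            chosen = np.concatenate(
                [rng.choice(idx, size=m, replace=True) for idx in class_indices]
            )
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                max_depth=self.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[chosen], y[chosen])
            self._bootstrap_counts.append((m, m))
            self.trees_.append(tree)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        total = np.zeros((X.shape[0], 2))
        for tree in self.trees_:
            proba = tree.predict_proba(X)
            # map tree class order onto (0, 1)
            for j, c in enumerate(tree.classes_):
                total[:, int(c)] += proba[:, j]
        return total / len(self.trees_)

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    @property
    def feature_importances_(self) -> np.ndarray:
        if not self.trees_:
            raise ValueError("model is not fitted")
        importances = np.mean([t.feature_importances_ for t in self.trees_], axis=0)
        total = importances.sum()
        return importances / total if total > 0 else importances


# ---------------------------------------------------------------------------
# splitting and cross-validation


def stratified_split(
    dataset: LabeledDataset, test_fraction: float = 0.25, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of a stratified train/test partition of the dataset."""
    y = dataset.labels
    if min(np.bincount(y, minlength=2)) < 2:
        raise ValueError("each class needs at least 2 members to split")
    indices = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        indices, test_size=test_fraction, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class FoldResult:
    scores: np.ndarray  # out-of-fold positive-class scores
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    auroc: float
    threshold: float | None = None
    tpr_at_threshold: float | None = None
    importances: np.ndarray | None = None


@dataclass
class CVResult:
    folds: list[FoldResult]
    feature_names: list[str]

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def auroc_mean(self) -> float:
        return float(np.mean([f.auroc for f in self.folds]))

    @property
    def auroc_sd(self) -> float:
        return float(np.std([f.auroc for f in self.folds], ddof=1))

    def mean_importances(self) -> np.ndarray:
        return np.mean([f.importances for f in self.folds], axis=0)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    n_folds: int = 5,
    seed: int | None = None,
    n_estimators: int = DEFAULT_N_TREES,
) -> CVResult:
    """Stratified k-fold CV of the balanced forest; out-of-fold ROC per fold."""
    y = np.asarray(y)
    if min(np.bincount(y, minlength=2)) < n_folds:
        raise ValueError(
            f"too few members of one class for {n_folds} stratified folds; "
            "reduce n_folds"
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(seed)
    folds: list[FoldResult] = []
    for fit_idx, val_idx in splitter.split(X, y):
        model = BalancedRandomForest(
            n_estimators=n_estimators, random_state=int(rng.integers(0, 2**31 - 1))
        )
        model.fit(X[fit_idx], y[fit_idx])
        scores = model.score_samples(X[val_idx])
        fpr, tpr, thresholds = roc_curve(y[val_idx], scores)
        folds.append(
            FoldResult(
                scores=scores,
                labels=y[val_idx],
                fpr=fpr,
                tpr=tpr,
                roc_thresholds=thresholds,
                auroc=float(roc_auc_score(y[val_idx], scores)),
                importances=model.feature_importances_,
            )
        )
    return CVResult(folds=folds, feature_names=list(feature_names))


def _fold_threshold(
    scores: np.ndarray, labels: np.ndarray, fpr_target: float
) -> tuple[float, float]:
    """Smallest score threshold with fold FPR <= target, and its TPR.

    Candidate thresholds are the observed scores (a prediction is positive
    when score >= threshold).  FPR is non-increasing in the threshold, so
    the smallest admissible threshold maximises TPR subject to the bound.
    When no negative score admits the target, a threshold just above the
    maximum negative score (FPR 0) is used.
    """
    negatives = scores[labels == 0]
    positives = scores[labels == 1]
    candidates = np.unique(scores)
    best = None
    for threshold in candidates:  # ascending
        fpr = float(np.mean(negatives >= threshold)) if negatives.size else 0.0
        if fpr <= fpr_target:
            best = float(threshold)
            break
    if best is None:
        best = float(negatives.max()) + 1e-9
    tpr = float(np.mean(positives >= best)) if positives.size else 0.0
    return best, tpr


def threshold_at_fpr(
    cv: CVResult, fpr_target: float = DEFAULT_FPR_TARGET
) -> tuple[float, float]:
    """Mean per-fold FPR-bounded threshold and mean TPR at those thresholds."""
    thresholds, tprs = [], []
    for fold in cv.folds:
        threshold, tpr = _fold_threshold(fold.scores, fold.labels, fpr_target)
        fold.threshold = threshold
        fold.tpr_at_threshold = tpr
        thresholds.append(threshold)
        tprs.append(tpr)
    return float(np.mean(thresholds)), float(np.mean(tprs))


def select_top_features(cv: CVResult) -> list[str]:
    """Upper quartile of features by mean cross-fold Gini importance.

    Features with mean importance >= the 75th percentile are retained;
    boundary ties are all kept, so an all-equal importance vector retains
    everything.
    """
    mean_importance = cv.mean_importances()
    cutoff = np.quantile(mean_importance, 0.75)
    keep = mean_importance >= cutoff
    return [name for name, kept in zip(cv.feature_names, keep) if kept]


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """(TPR + TNR) / 2 — accuracy averaged over the two classes."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    neg = y_true == 0
    tpr = float(np.mean(y_pred[pos] == 1)) if pos.any() else 0.0
    tnr = float(np.mean(y_pred[neg] == 0)) if neg.any() else 0.0
    return (tpr + tnr) / 2


# ---------------------------------------------------------------------------
# model bundle


@dataclass
class ModelBundle:
    """A trained classifier with everything needed to score new sequences."""

    scheme_name: str
    ensemble: BalancedRandomForest
    retained_features: list[str]
    threshold_high: float
    cv_metrics: dict[str, float]
    scaling: pd.DataFrame
    registry: FeatureRegistry = DEFAULT_REGISTRY
    threshold_low: float = 0.5
    seed: int | None = None

    def score_table(self, table: FeatureTable) -> np.ndarray:
        """Scores for an unscaled feature table (bundle scaling applied)."""
        scaled = table.apply_scaling(self.scaling)
        X = scaled.subset(self.retained_features).values
        return self.ensemble.score_samples(X)

    def score_records(self, records: Sequence[ProteinRecord]) -> np.ndarray:
        table = extract_features(records, registry=self.registry, scale=False)
        return self.score_table(table)

    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.ensemble, out_dir / "ensemble.joblib")
        pd.Series(self.retained_features, name="feature").to_csv(
            out_dir / "retained_features.tsv", sep="\t", index=False
        )
        self.scaling.to_csv(out_dir / "scaling.tsv", sep="\t", index_label="feature")
        metadata = {
            "scheme_name": self.scheme_name,
            "threshold_high": self.threshold_high,
            "threshold_low": self.threshold_low,
            "seed": self.seed,
            "cv_metrics": self.cv_metrics,
            "registry_version": self.registry.version,
        }
        (out_dir / "metadata.json").write_text(json.dumps(metadata, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "ModelBundle":
        in_dir = Path(in_dir)
        metadata = json.loads((in_dir / "metadata.json").read_text())
        ensemble = joblib.load(in_dir / "ensemble.joblib")
        retained = pd.read_csv(in_dir / "retained_features.tsv", sep="\t")[
            "feature"
        ].tolist()
        scaling = pd.read_csv(in_dir / "scaling.tsv", sep="\t", index_col="feature")
        return cls(
            scheme_name=metadata["scheme_name"],
            ensemble=ensemble,
            retained_features=retained,
            threshold_high=metadata["threshold_high"],
            threshold_low=metadata["threshold_low"],
            cv_metrics=metadata["cv_metrics"],
            scaling=scaling,
            seed=metadata["seed"],
        )


@dataclass
class TestReport:
    balanced_accuracy_at_threshold: float
    balanced_accuracy_at_half: float
    test_fpr_at_threshold: float
    test_tpr_at_threshold: float
    n_test: int


def finalize_model(
    dataset: LabeledDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    cv: CVResult,
    retained_features: Sequence[str],
    threshold_high: float,
    seed: int | None = None,
    n_estimators: int = DEFAULT_N_TREES,
) -> tuple[ModelBundle, TestReport]:
    """Refit on all training data with retained features; report on test data."""
    table = dataset.feature_table
    retained = list(retained_features)
    X = table.subset(retained).values
    y = dataset.labels
    model = BalancedRandomForest(n_estimators=n_estimators, random_state=seed)
    model.fit(X[train_idx], y[train_idx])

    test_scores = model.score_samples(X[test_idx])
    y_test = y[test_idx]
    pred_high = (test_scores >= threshold_high).astype(int)
    pred_low = (test_scores >= 0.5).astype(int)
    negatives = y_test == 0
    positives = y_test == 1
    report = TestReport(
        balanced_accuracy_at_threshold=balanced_accuracy(y_test, pred_high),
        balanced_accuracy_at_half=balanced_accuracy(y_test, pred_low),
        test_fpr_at_threshold=(
            float(np.mean(test_scores[negatives] >= threshold_high))
            if negatives.any()
            else 0.0
        ),
        test_tpr_at_threshold=(
            float(np.mean(test_scores[positives] >= threshold_high))
            if positives.any()
            else 0.0
        ),
        n_test=len(test_idx),
    )
    bundle = ModelBundle(
        scheme_name=dataset.scheme.name,
        ensemble=model,
        retained_features=retained,
        threshold_high=threshold_high,
        cv_metrics={
            "auroc_mean": cv.auroc_mean,
            "auroc_sd": cv.auroc_sd,
            "tpr_at_threshold": float(
                np.mean([f.tpr_at_threshold for f in cv.folds])
            ),
        },
        scaling=(
            table.scaling
            if table.scaling is not None
            else FeatureTable(table.frame).fit_scaling().scaling
        ),
        seed=seed,
    )
    return bundle, report


def run_training_pipeline(
    dataset: LabeledDataset,
    fpr_target: float = DEFAULT_FPR_TARGET,
    test_fraction: float = 0.25,
    n_folds: int = 5,
    seed: int | None = None,
    n_estimators: int = DEFAULT_N_TREES,
) -> tuple[ModelBundle, TestReport, CVResult]:
    """Full pipeline: split, cross-validate, calibrate, select, finalise.

    One master seed fans out deterministically to the split, the fold
    assignment and every tree's bootstrap.
    """
    rng = np.random.default_rng(seed)
    split_seed, cv_seed, final_seed = (
        int(rng.integers(0, 2**31 - 1)) for _ in range(3)
    )
    train_idx, test_idx = stratified_split(dataset, test_fraction, split_seed)
    table = dataset.feature_table
    X = table.values
    y = dataset.labels
    cv = cross_validate(
        X[train_idx],
        y[train_idx],
        table.feature_names,
        n_folds=n_folds,
        seed=cv_seed,
        n_estimators=n_estimators,
    )
    threshold_high, _ = threshold_at_fpr(cv, fpr_target)
    retained = select_top_features(cv)
    bundle, report = finalize_model(
        dataset,
        train_idx,
        test_idx,
        cv,
        retained,
        threshold_high,
        seed=final_seed,
        n_estimators=n_estimators,
    )
    return bundle, report, cv


# ---------------------------------------------------------------------------
# bias estimation


@dataclass
class BiasReport:
    """Mean and distribution of modified-minus-unmodified score differences."""

    dataset_name: str
    mean_difference: float
    differences: pd.Series  # indexed by protein id
    modified_scores: pd.Series
    unmodified_scores: pd.Series

    def summary(self) -> dict[str, float]:
        return {
            "mean_difference": self.mean_difference,
            "sd_difference": float(self.differences.std(ddof=1))
            if len(self.differences) > 1
            else 0.0,
            "n_pairs": float(len(self.differences)),
        }

    def to_tsv(self, path) -> None:
        frame = pd.DataFrame(
            {
                "modified_score": self.modified_scores,
                "unmodified_score": self.unmodified_scores,
                "difference": self.differences,
            }
        )
        frame.to_csv(path, sep="\t", index_label="protein_id")


def estimate_bias(
    bundle: ModelBundle,
    modified: Sequence[ProteinRecord],
    unmodified: Sequence[ProteinRecord],
    dataset_name: str = "",
) -> BiasReport:
    """Score matched modified/unmodified pairs and summarise the differences.

    Pairing is by protein id; both collections must contain exactly the
    same ids.  The reported mean is signed (modified − unmodified), so a
    positive value means modification inflates scores.
    """
    modified_ids = [r.id for r in modified]
    unmodified_ids = [r.id for r in unmodified]
    if sorted(modified_ids) != sorted(unmodified_ids):
        only_modified = set(modified_ids) - set(unmodified_ids)
        only_unmodified = set(unmodified_ids) - set(modified_ids)
        raise ValueError(
            f"unmatched pair ids: modified-only {sorted(only_modified)[:5]}, "
            f"unmodified-only {sorted(only_unmodified)[:5]}"
        )
    modified_scores = pd.Series(
        bundle.score_records(modified), index=modified_ids
    ).sort_index()
    unmodified_scores = pd.Series(
        bundle.score_records(unmodified), index=unmodified_ids
    ).sort_index()
    differences = modified_scores - unmodified_scores
    return BiasReport(
        dataset_name=dataset_name,
        mean_difference=float(differences.mean()),
        differences=differences,
        modified_scores=modified_scores,
        unmodified_scores=unmodified_scores,
    )
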