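"""Replicated simulation studies of the training pipeline.

These drive the calibration checks: generate a synthetic two-class
benchmark (compositionally shifted LSP-like positives against background
negatives), run the full split / cross-validate / calibrate / finalise
pipeline, and measure the held-out false-positive rate achieved at the
cross-validation-derived threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lspsuite.datasets import SCHEMES, LabeledDataset
from lspsuite.features import extract_features
from lspsuite.synth import SynthConfig, make_benchmark
from lspsuite.training import (
    DEFAULT_FPR_TARGET,
    DEFAULT_N_TREES,
    run_training_pipeline,
)


def benchmark_dataset(
    n_positive: int = 60,
    n_negative: int = 600,
    seed: int = 0,
    config: SynthConfig | None = None,
) -> LabeledDataset:
    """Generate and featurise one LSP-like vs background benchmark."""
    records, labels = make_benchmark(n_positive, n_negative, seed=seed, config=config)
    table = extract_features(records, scale=True)
    return LabeledDataset(
        scheme=SCHEMES["LSPpred1"],
        records=records,
        labels=labels,
        feature_table=table,
        seed=seed,
    )


@dataclass
class CalibrationStudy:
    """Replicate-level results of the FPR-calibration simulation."""

    test_fprs: list[float]
    test_tprs: list[float]
    thresholds: list[float]
    aurocs: list[float]

    @property
    def mean_fpr(self) -> float:
        return float(np.mean(self.test_fprs))

    @property
    def fpr_standard_error(self) -> float:
        if len(self.test_fprs) < 2:
            return 0.0
        return float(np.std(self.test_fprs, ddof=1) / np.sqrt(len(self.test_fprs)))


def fpr_calibration_study(
    n_replicates: int = 20,
    n_positive: int = 60,
    n_negative: int = 600,
    seed: int = 0,
    fpr_target: float = DEFAULT_FPR_TARGET,
    n_estimators: int = DEFAULT_N_TREES,
) -> CalibrationStudy:
    """Held-out FPR at the calibrated threshold over replicate pipelines.

    Each replicate draws a fresh fixture and a fresh pipeline seed from the
    master seed, so replicates are independent and the whole study is
    reproducible.
    """
    rng = np.random.default_rng(seed)
    fprs: list[float] = []
    tprs: list[float] = []
    thresholds: list[float] = []
    aurocs: list[float] = []
    for _ in range(n_replicates):
        data_seed = int(rng.integers(0, 2**31 - 1))
        pipe_seed = int(rng.integers(0, 2**31 - 1))
        dataset = benchmark_dataset(n_positive, n_negative, seed=data_seed)
        bundle, report, cv = run_training_pipeline(
            dataset, fpr_target=fpr_target, seed=pipe_seed,
            n_estimators=n_estimators,
        )
        fprs.append(report.test_fpr_at_threshold)
        tprs.append(report.test_tpr_at_threshold)
        thresholds.append(bundle.threshold_high)
        aurocs.append(cv.auroc_mean)
    return CalibrationStudy(
        test_fprs=fprs, test_tprs=tprs, thresholds=thresholds, aurocs=aurocs
    )
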