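import numpy as np
import pytest

from lspsuite.datasets import SCHEMES, LabeledDataset
from lspsuite.features import extract_features
from lspsuite.synth import SynthConfig, generate_fixture, make_benchmark
from lspsuite.training import run_training_pipeline


@pytest.fixture(scope="session")
def fixture_proteome():
    """Zero-noise synthetic proteome with wired evidence and ground truth."""
    return generate_fixture(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def benchmark_dataset():
    """LSP-like vs background benchmark (60/600) with extracted features."""
    records, labels = make_benchmark(60, 600, seed=101)
    table = extract_features(records, scale=True)
    return LabeledDataset(
        scheme=SCHEMES["LSPpred1"],
        records=records,
        labels=labels,
        feature_table=table,
        seed=101,
    )


@pytest.fixture(scope="session")
def trained_pipeline(benchmark_dataset):
    """One full training run shared by learnability / prediction tests."""
    bundle, report, cv = run_training_pipeline(benchmark_dataset, seed=101)
    return bundle, report, cv
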