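import numpy as np
import pandas as pd
import pytest

from dapsel import (
    Comparison,
    IntensityMatrix,
    SampleMeta,
    SimConfig,
    build_comparisons,
    correct_batch,
    fit_lmm,
    generate_dataset,
)


@pytest.fixture(scope="session")
def factorial_dataset():
    """Standard 4-group x 3-replicate synthetic dataset with known truth."""
    cfg = SimConfig(
        n_groups=4, n_reps_per_group=3, n_features=300, n_signal=12,
        effect_size=2.0, seed=101,
    )
    data, truth = generate_dataset(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def two_group_dataset():
    """Two groups of six samples (the 12-sample two-class layout)."""
    cfg = SimConfig(
        n_groups=2, n_reps_per_group=6, n_features=300, n_signal=10,
        effect_size=2.0, seed=77,
    )
    data, truth = generate_dataset(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def corrected_two_group(two_group_dataset):
    cfg, data, truth = two_group_dataset
    adj = correct_batch(data, fit_lmm(data))
    cmp = build_comparisons(data.samples)[0]
    return adj, cmp, truth


def make_matrix(values: np.ndarray, groups, replicates=None, feature_ids=None):
    """Small helper to build an IntensityMatrix from a plain array."""
    n = values.shape[1]
    replicates = replicates or list(range(1, n + 1))
    feature_ids = feature_ids or [f"f{k}" for k in range(values.shape[0])]
    samples = [
        SampleMeta(f"s{i}", groups[i], groups[i], "none", replicates[i])
        for i in range(n)
    ]
    df = pd.DataFrame(values, index=feature_ids, columns=[f"s{i}" for i in range(n)])
    return IntensityMatrix(df, samples)


@pytest.fixture()
def toy_two_group():
    """3 features x 6 samples, groups A (first 3) vs B (last 3)."""
    rng = np.random.default_rng(0)
    vals = rng.normal(10.0, 1.0, size=(3, 6))
    data = make_matrix(vals, ["A"] * 3 + ["B"] * 3)
    return data, Comparison("A_vs_B", "A", "B")
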