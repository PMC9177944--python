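import numpy as np
import pandas as pd
import pytest

from ifnsig.expression import CountMatrix, filter_low_expressed, normalize
from ifnsig.synthetic import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def default_cohort():
    """One default-structure cohort (23 CTL + 25 FM) at 2000 genes."""
    cfg = SimConfig(n_genes=2000, seed=0)
    counts, truth = simulate_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def normalized_cohort(default_cohort):
    cfg, counts, truth = default_cohort
    filtered = filter_low_expressed(counts)
    log_norm = normalize(filtered, scale="log2")
    return cfg, filtered, truth, log_norm


@pytest.fixture
def tiny_counts():
    """3 genes x 4 samples with hand-checkable values."""
    df = pd.DataFrame(
        [[10, 20, 10, 20], [5, 10, 5, 10], [100, 200, 100, 200]],
        index=["g1", "g2", "g3"],
        columns=["c1", "c2", "f1", "f2"],
    )
    groups = pd.Series(["CTL", "CTL", "FM", "FM"], index=df.columns)
    return CountMatrix(df, groups)
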