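import numpy as np
import pandas as pd
import pytest

import txmod


@pytest.fixture
def small_counts():
    """5 genes x 4 samples, hand-checkable."""
    genes = ["g1", "g2", "g3", "g4", "g5"]
    samples = ["s1", "s2", "s3", "s4"]
    counts = np.array([
        [10, 0, 3, 7],
        [0, 0, 0, 0],
        [5, 5, 5, 5],
        [1, 2, 3, 4],
        [100, 200, 50, 25],
    ])
    return txmod.CountMatrix(genes, samples, counts)


@pytest.fixture
def small_metadata():
    return txmod.validate_sample_table(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "compartment": ["blood", "blood", "BAL", "BAL"],
        "condition": ["HIVneg", "HIVpos", "HIVneg", "HIVpos"],
    }))


@pytest.fixture(scope="session")
def ref_sim():
    """Sorted-cell reference simulation at generator defaults."""
    cfg = txmod.GeneratorConfig(seed=11)
    counts, meta, truth = txmod.simulate_reference_profiles(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def cohort_sim():
    """Bulk cohort simulation at generator defaults."""
    cfg = txmod.GeneratorConfig(seed=11)
    counts, meta, truth = txmod.simulate_bulk_cohort(cfg)
    return cfg, counts, meta, truth


@pytest.fixture
def random_expr():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(50)]
    samples = [f"s{j}" for j in range(12)]
    values = rng.normal(5.0, 2.0, size=(50, 12))
    return txmod.ExpressionMatrix(genes, samples, values)
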