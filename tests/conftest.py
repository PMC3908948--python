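import numpy as np
import pandas as pd
import pytest

from lcmsnorm import FeatureMatrix, SampleTable, SimConfig, simulate_eics, simulate_experiment


@pytest.fixture
def small_matrix():
    """3 features x 4 samples with hand-checkable values."""
    values = np.array([
        [2.0, 4.0, 1.0, 3.0],
        [6.0, 12.0, 4.0, 8.0],
        [10.0, 20.0, 6.0, 18.0],
    ])
    return FeatureMatrix(values, ["f1", "f2", "f3"], ["s1", "s2", "s3", "s4"],
                         feature_rt=np.array([100.0, 300.0, 500.0]),
                         feature_mz=np.array([150.0, 350.0, 550.0]))


@pytest.fixture
def qc_metadata():
    """8 samples: 4 QC at orders 1,3,5,7 and 4 cases in between."""
    rows = []
    for t in range(1, 9):
        rows.append({"sample_id": f"s{t}", "analysis_order": t, "batch": "B1",
                     "experiment": "F", "group": "QC" if t % 2 == 1 else "case"})
    return SampleTable(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def sim_small():
    """One small simulated experiment shared across read-only tests."""
    cfg = SimConfig(p=12, seed=7, n_batches=1)
    fm, st, truth = simulate_experiment(cfg)
    return cfg, fm, st, truth


@pytest.fixture(scope="session")
def sim_eics_small():
    cfg = SimConfig(p=4, seed=11, n_batches=1, n_scans=11)
    fm, st, truth = simulate_experiment(cfg)
    eics = simulate_eics(cfg, fm, st, truth)
    return cfg, fm, st, truth, eics
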