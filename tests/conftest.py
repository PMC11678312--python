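import numpy as np
import pandas as pd
import pytest

from combatcv.cohort import CohortConfig, FeatureTable, ScannerSpec, generate_cohort


@pytest.fixture
def small_config():
    """Three mid-sized scanners, 16 features, a modest real group effect."""
    return CohortConfig(
        scanners=(
            ScannerSpec("A", 15, 12, gamma_loc=0.8, delta_scale=1.3),
            ScannerSpec("B", 12, 14, gamma_loc=-0.5, delta_scale=0.8),
            ScannerSpec("C", 14, 11, gamma_loc=0.2, delta_scale=1.1),
        ),
        n_features_fs=6, n_features_doj=10, group_effect_size=0.5, seed=11)


@pytest.fixture
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_table(X, scanner, group, age=None, sex=None, prefix="FS_mid"):
    """Hand-rolled FeatureTable from plain arrays (midline feature names)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    df = pd.DataFrame({
        "scanner": list(scanner),
        "group": list(group),
        "age": age if age is not None else np.full(n, 60.0),
        "sex": sex if sex is not None else ["M"] * n,
        "etiv": np.full(n, 1.5e6),
    }, index=pd.Index([f"s{i:04d}" for i in range(n)], name="subject_id"))
    feat = pd.DataFrame(X, index=df.index,
                        columns=[f"{prefix}{j:03d}" for j in range(X.shape[1])])
    return FeatureTable(pd.concat([df, feat], axis=1))
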