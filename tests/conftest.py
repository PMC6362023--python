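import numpy as np
import pandas as pd
import pytest

from devassoc.config import SimulationConfig


@pytest.fixture
def tiny_config():
    """Small synthetic study for fast structural tests."""
    return SimulationConfig(
        n_genes=60,
        subjects_per_stage=2,
        stages=("S1", "S2", "S3"),
        region_groups={"ctx": ("R1", "R2"), "sub": ("R3",)},
        zero_gene_fraction=0.1,
        seed=11,
    )


@pytest.fixture
def toy_samples():
    """Six samples, one region, two stages, varied covariates."""
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(6)],
            "subject_id": [f"d{i}" for i in range(6)],
            "age": [0, 0, 0, 1, 1, 1.0],
            "stage": ["A", "A", "A", "B", "B", "B"],
            "region": ["R"] * 6,
            "RIN": [7.1, 8.0, 8.9, 7.5, 8.4, 9.3],
            "ethnicity": ["E1", "E2", "E1", "E1", "E2", "E2"],
            "sex": ["F", "M", "F", "M", "F", "M"],
        }
    )


def ols_normal_equations(X: np.ndarray, y: np.ndarray):
    """Independent OLS oracle: solve X'X b = X'y directly."""
    b = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ b
    return b, resid
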