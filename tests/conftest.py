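import numpy as np
import pytest

from t2drisk import CohortConfig, T2DRiskModel, generate_cohort
from t2drisk.fuzzy import label_table


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (n=1939) at a fixed seed."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def labeled_default(default_cohort):
    labeled, scaler = label_table(default_cohort)
    return labeled


@pytest.fixture(scope="session")
def fitted_results(default_cohort):
    """Full model fit (label -> split -> train -> calibrate -> evaluate)."""
    return T2DRiskModel(default_cohort, seed=1).fit()


@pytest.fixture()
def blobs():
    """Well-separated 2-feature Gaussian blobs, one per class, in [0,1]."""
    rng = np.random.default_rng(7)
    centers = {"A": (0.15, 0.15), "B": (0.85, 0.15), "C": (0.15, 0.85), "D": (0.85, 0.85)}
    X, y = [], []
    for cls, (cx, cy) in centers.items():
        X.append(rng.normal((cx, cy), 0.05, size=(60, 2)))
        y += [cls] * 60
    return np.clip(np.vstack(X), 0, 1), np.array(y)
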