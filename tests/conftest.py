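import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import goadf

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_matrix(values: np.ndarray, n_case: int, feature_ids=None) -> goadf.ExpressionMatrix:
    """Wrap an array as an ExpressionMatrix with the first n_case columns
    labelled case."""
    n_features, n_samples = values.shape
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_features)]
    samples = [f"s{j}" for j in range(n_samples)]
    labels = pd.Series(
        [1] * n_case + [0] * (n_samples - n_case), index=samples, name="label"
    )
    return goadf.ExpressionMatrix(
        pd.DataFrame(values, index=feature_ids, columns=samples), labels
    )


@pytest.fixture
def toy_matrix() -> goadf.ExpressionMatrix:
    """3 features x 4 samples, 2 case / 2 control."""
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(size=(3, 4)), n_case=2)


@pytest.fixture
def balanced_matrix() -> goadf.ExpressionMatrix:
    """20 null features, 10/10 samples — enough for nested splits."""
    rng = np.random.default_rng(7)
    return make_matrix(rng.normal(size=(20, 20)), n_case=10)


@pytest.fixture(scope="session")
def small_simulated() -> goadf.SimulatedDataset:
    """Compact planted-marker cohort reused by slower end-to-end tests."""
    config = goadf.SimulationConfig(
        n_features=120, n_case=40, n_control=40, n_modules=4,
        module_size=5, n_markers=4, delta=1.5, seed=11,
    )
    return goadf.simulate(config)
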