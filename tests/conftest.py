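import numpy as np
import pandas as pd
import pytest

from epcat.copa_outlier import ExpressionDataset
from epcat.synthetic_data import SimulationConfig, generate_expression_datasets


@pytest.fixture(scope="session")
def sim():
    """Default simulation shared across tests (seed frozen)."""
    config = SimulationConfig(seed=7)
    datasets, truth = generate_expression_datasets(config)
    return config, datasets, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_dataset(
    n_control: int = 5,
    n_cancer: int = 10,
    n_features: int = 3,
    seed: int = 0,
    dataset_id: str = "T",
) -> ExpressionDataset:
    """Tiny dataset with one control and one cancer group."""
    rng = np.random.default_rng(seed)
    samples = [f"c{i}" for i in range(n_control)] + [
        f"k{i}" for i in range(n_cancer)
    ]
    matrix = pd.DataFrame(
        rng.normal(5, 1, size=(n_features, len(samples))),
        index=[f"TC{i}" for i in range(n_features)],
        columns=samples,
    )
    groups = {s: ("ctrl" if s.startswith("c") else "tum") for s in samples}
    return ExpressionDataset(
        dataset_id, matrix, groups, {"ctrl": "control", "tum": "cancer"}
    )
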