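import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from veh import ExpressionDataset, make_separable_toy, preprocess

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_dataset():
    """3 samples x 2 genes with one missing entry."""
    return ExpressionDataset(
        values=np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]]),
        feature_ids=["g1", "g2"],
        labels=np.array(["a", "b", "a"]),
        name="tiny",
    )


@pytest.fixture
def toy():
    """Separable fixture: gene 0 encodes the class, preprocessed."""
    ds, truth = make_separable_toy(n_samples=60, n_genes=40, seed=1)
    return preprocess(ds), truth


def informative_ids(truth):
    return {f"g{j}" for j in truth.informative_indices}
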