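import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kfselm.data_io import FeatureDataset
from kfselm.synthetic import SyntheticSpec, generate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def separable_toy():
    """Two well-separated Gaussian classes in 2 dimensions, N=40."""
    rng = np.random.default_rng(7)
    n_per = 20
    a = rng.normal([-2.0, -2.0], 0.3, size=(n_per, 2))
    b = rng.normal([2.0, 2.0], 0.3, size=(n_per, 2))
    X = np.vstack([a, b])
    labels = ["neg"] * n_per + ["pos"] * n_per
    return FeatureDataset.from_features(X, labels)


@pytest.fixture
def small_conn_dataset():
    """Small connectivity-like dataset: 10 regions (45 edges), 5 planted."""
    spec = SyntheticSpec(
        n_regions=10, n_per_class=30, informative_edges=5,
        effect_size=1.5, seed=42,
    )
    dataset, truth = generate_dataset(spec)
    return dataset, truth
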