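import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sffstree as st

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pair_fixture():
    """Complementary-pair dataset at a separating effect size (5 sigma)."""
    ds, truth = st.generate(st.pair_scenario(seed=0, effect=5.0, n_probes=100))
    return ds, truth


@pytest.fixture(scope="session")
def small_pair_fixture():
    ds, truth = st.generate(st.pair_scenario(seed=0, effect=5.0, n_probes=20))
    return ds, truth


@pytest.fixture()
def toy_dataset():
    """Six samples, two probes, modest separation."""
    values = np.array(
        [
            [7.1, 8.9, 9.4, 6.8, 7.0, 9.1],
            [5.0, 5.2, 4.9, 5.1, 5.3, 4.8],
        ]
    )
    return st.ExpressionDataset(
        probe_ids=["gA", "gB"],
        sample_ids=[f"s{i}" for i in range(6)],
        labels=["normal", "tumor", "tumor", "normal", "normal", "tumor"],
        values=values,
    )


def random_labeled_matrix(rng, n, f, balanced=False):
    """Random samples x features matrix plus tumor/normal labels."""
    x = rng.normal(8.0, 1.0, size=(n, f))
    if balanced:
        nt = n // 2
    else:
        nt = int(rng.integers(2, n - 1))
    labels = ["tumor"] * nt + ["normal"] * (n - nt)
    return x, labels


def dataset_from_matrix(x, labels):
    n, f = x.shape
    return st.ExpressionDataset(
        probe_ids=[f"g{j}" for j in range(f)],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=list(labels),
        values=np.asarray(x).T.copy(),
    )
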