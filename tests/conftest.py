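import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ggapdc
from ggapdc.synth import SynthSpec, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


def random_records(rng, n, length_low=10, length_high=500, prefix="r"):
    """Uniform-background records for oracle comparisons."""
    records = []
    for i in range(n):
        L = int(rng.integers(length_low, length_high + 1))
        seq = "".join(rng.choice(list(ggapdc.ALPHABET), size=L))
        records.append(ggapdc.ProteinRecord(f"{prefix}{i}", seq))
    return records


@pytest.fixture(scope="session")
def planted_dataset():
    """Strong planted signal at g*=6: near-separable two-class data."""
    spec = SynthSpec(
        n_pos=40, n_neg=60, length_range=(120, 400), g_star=6,
        effect=0.03, seed=11,
    )
    records, labels, truth = generate_dataset(spec)
    return records, labels, truth


@pytest.fixture(scope="session")
def planted_matrix(planted_dataset):
    records, labels, _ = planted_dataset
    return ggapdc.build_feature_matrix(records, labels, 6)


@pytest.fixture(scope="session")
def null_matrix():
    """No class signal: both classes drawn from the same background."""
    spec = SynthSpec(n_pos=30, n_neg=30, length_range=(100, 300), effect=0.0, seed=7)
    records, labels, _ = generate_dataset(spec)
    return ggapdc.build_feature_matrix(records, labels, 4)
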