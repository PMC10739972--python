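import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hfens.core_data import ClinicalTable, FeatureSpec
from hfens.synthetic_data import GeneratorConfig, generate

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_table(X, y, kinds=None) -> ClinicalTable:
    """Ad-hoc unbounded table for algorithm-level tests."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    kinds = kinds or ["continuous"] * X.shape[1]
    specs = tuple(
        FeatureSpec(f"f{i}", k, valid_range=(0, 1) if k == "binary" else (-np.inf, np.inf))
        for i, k in enumerate(kinds)
    )
    return ClinicalTable(X=X, y=np.asarray(y, dtype=int), specs=specs)


def random_two_class_table(rng, n_max=60, d_max=4) -> ClinicalTable:
    """Random small table guaranteed to contain both classes."""
    n = int(rng.integers(6, n_max + 1))
    d = int(rng.integers(1, d_max + 1))
    X = rng.normal(size=(n, d))
    y = (rng.random(n) < rng.uniform(0.15, 0.5)).astype(int)
    if y.sum() < 2:
        y[:2] = 1
    if (1 - y).sum() < 2:
        y[-2:] = 0
    return make_table(X, y)


@pytest.fixture(scope="session")
def default_table():
    """The default synthetic clinical table (299 records, 203/96)."""
    return generate(GeneratorConfig(seed=0))


@pytest.fixture
def table_factory():
    return make_table
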