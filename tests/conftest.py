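import numpy as np
import pytest

from spipls import WineDataset, default_config, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The study-shaped synthetic fixture: 110 wines, 52 assays, 5 outliers."""
    return generate_dataset(default_config(seed=0))


@pytest.fixture(scope="session")
def clean_dataset():
    """Same shape without injected outliers."""
    return generate_dataset(default_config(seed=0, outlier_fraction=0.0))


def make_null_dataset(seed: int, n: int = 60, p: int = 20) -> WineDataset:
    """y independent of X, two strata."""
    rng = np.random.default_rng(seed)
    return WineDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        strata=["A"] * (n // 2) + ["B"] * (n - n // 2),
        predictor_names=[f"v{j}" for j in range(p)],
        X=rng.standard_normal((n, p)),
        y=rng.standard_normal(n),
    )


def random_regression(seed: int, n: int, p: int, noise: float = 0.1):
    """Small random full-rank regression problem with a known linear signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = rng.standard_normal(p)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y
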