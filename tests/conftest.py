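import numpy as np
import pytest

from cmi2ni import GaussianModel


def random_spd_model(rng: np.random.Generator, dim: int, names=None) -> GaussianModel:
    """A well-conditioned random SPD covariance with named variables."""
    a = rng.normal(size=(dim, dim))
    cov = a @ a.T + dim * np.eye(dim)
    names = names or tuple(f"v{i}" for i in range(dim))
    return GaussianModel(tuple(names), rng.normal(size=dim), cov)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
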