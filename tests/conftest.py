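import numpy as np
import pytest

import s3cgan.autodiff as ad
from s3cgan.synthetic_data import make_fixture_set
from s3cgan.training import TrainingConfig


@pytest.fixture(scope="session")
def tiny_fixtures():
    """Small two-style fixture suite shared by fast tests."""
    return make_fixture_set(n_per_domain=24, size=64, seed=11, n_paired=6,
                            n_pretrain=24)


@pytest.fixture(scope="session")
def mini_fixtures():
    """32-pixel patches for the quickest smoke checks."""
    return make_fixture_set(n_per_domain=12, size=32, seed=3, n_paired=4,
                            n_pretrain=12)


@pytest.fixture
def smoke_cfg():
    return TrainingConfig.desk_scale(steps_classifier=60, steps_gan=5, seed=0)


class LinearCritic:
    """Test double: D(x) = <u, x> per sample (score is a 1x1 map)."""

    def __init__(self, u: np.ndarray):
        self.u = ad.Tensor(np.asarray(u, dtype=np.float64))

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        prod = ad.mul(x, self.u)
        n = x.shape[0]
        flat = ad.reshape(prod, (n, -1))
        return ad.reshape(ad.sum_(flat, axis=1), (n, 1, 1))


class ConstantCritic:
    """Test double: D(x) = c everywhere, zero input gradient."""

    def __init__(self, c: float, map_side: int = 1):
        self.c = float(c)
        self.side = map_side

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        n = x.shape[0]
        base = ad.mul(ad.sum_(x), 0.0)  # keeps the tape connected
        grid = ad.broadcast_to(ad.reshape(base, (1, 1, 1)), (n, self.side, self.side))
        return ad.add(grid, ad.Tensor(self.c))


class QuadraticCritic:
    """Test double: D(x) = sum(a * x^2) + <b, x> per sample."""

    def __init__(self, a: np.ndarray, b: np.ndarray):
        self.a = ad.Tensor(np.asarray(a, dtype=np.float64))
        self.b = ad.Tensor(np.asarray(b, dtype=np.float64))

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        n = x.shape[0]
        term = ad.add(ad.mul(ad.mul(x, x), self.a), ad.mul(x, self.b))
        return ad.reshape(ad.sum_(ad.reshape(term, (n, -1)), axis=1), (n, 1, 1))
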