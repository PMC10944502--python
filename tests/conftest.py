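"""Shared fixtures: tiny cohorts, shrunken network architectures, and stub
generative models used to exercise generation/controller logic without the
cost of real GAN training."""

from __future__ import annotations

import numpy as np
import pytest

from glucogan.cohort import make_cohort
from glucogan.gan import TrainConfig, loo_train
from glucogan.preprocessing import SignalNormalizer

#: shrunken architecture for desk-scale GAN tests
SMALL_ARCH = dict(
    critic_channels=(8, 16, 16, 8, 1),
    critic_kernels=(4, 4, 3, 1, 1),
    critic_strides=(2, 2, 1, 1, 1),
    gen_base_channels=4,
    gen_channels=(8, 8, 4, 1),
)


def identity_normalizers() -> dict[str, SignalNormalizer]:
    """Normalizers mapping [0, 1] onto itself (transform is the identity)."""
    return {k: SignalNormalizer.from_range(0.0, 1.0) for k in ("pi", "ra", "bg")}


class StubModel:
    """Generative-model stand-in with a pluggable window function."""

    def __init__(self, window_fn, shift: int = 18, normalizers=None):
        self.window_fn = window_fn
        self.shift = shift
        self.normalizers = normalizers or identity_normalizers()

    def generate_windows(self, pi_norm, ra_norm, Z):
        pi_norm = np.asarray(pi_norm, float)
        ra_norm = np.asarray(ra_norm, float)
        return self.window_fn(pi_norm, ra_norm, np.asarray(Z, float))


def constant_stub(value: float, shift: int = 18) -> StubModel:
    return StubModel(
        lambda pi, ra, Z: np.full((len(pi), shift), value), shift=shift
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_cohort(2, 2, seed=11)


@pytest.fixture(scope="session")
def toy_models(tiny_cohort):
    """Leave-one-out models trained at desk scale (small nets, few epochs)."""
    cfg = TrainConfig(epochs=3, lambda_l2=50.0, lr=1e-3, d_z=8, seed=5)
    return loo_train(tiny_cohort, cfg, **SMALL_ARCH)


@pytest.fixture(scope="session")
def coupled_logistic_maps():
    """Unidirectionally coupled logistic maps (x drives y, coupling 0.15)."""
    n, burn = 1100, 100
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = 0.4, 0.2
    for t in range(n - 1):
        x[t + 1] = x[t] * (3.8 - 3.8 * x[t])
        y[t + 1] = y[t] * (3.5 - 3.5 * y[t] - 0.15 * x[t])
    return x[burn:], y[burn:]
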