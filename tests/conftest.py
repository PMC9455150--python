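import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def random_spd(rng):
    """Factory for random SPD matrices with well-separated eigenvalues."""

    def make(p: int, seed: int | None = None) -> np.ndarray:
        r = np.random.default_rng(seed) if seed is not None else rng
        A = r.standard_normal((p, p))
        return A @ A.T + p * np.eye(p)

    return make


@pytest.fixture
def circle_data():
    """Latent-Gaussian circle-model data (identity warps), cached per session."""
    from npnchol.simulate import PrecisionSpec, gen_dataset, gen_precision

    omega = gen_precision(PrecisionSpec(kind="circle", p=10))
    Y, X, truth, _ = gen_dataset(omega, 200, seed=7, families="identity")
    return Y - Y.mean(axis=0), truth, omega
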