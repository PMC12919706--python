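import numpy as np
import pytest

from gridreg import PhantomSpec, make_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_pair():
    """One 32-cubed synthetic case shared across read-only tests."""
    return make_pair(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def scaled_down_study():
    """The desk-scale study: adaptive training on 40 pairs, 10 held out.

    Trained once per session and shared by the end-to-end tests (training
    dominates the suite's runtime).
    """
    from gridreg.pipeline import RegistrationConfig, train

    pairs = [make_pair(PhantomSpec(seed=5000 + i)) for i in range(50)]
    cfg = RegistrationConfig(epochs=10, batch_size=4, learning_rate=1e-4,
                             seed=0)
    result = train(pairs[:40], cfg)
    return result, pairs[40:]


def finite_difference_grad(f, x, eps=1e-5):
    """Central finite-difference gradient of scalar f at array x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g
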