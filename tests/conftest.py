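import numpy as np
import pytest

import critnet as cn


@pytest.fixture(scope="session")
def line64():
    return cn.build_line_connectivity(64, 1.0)


@pytest.fixture(scope="session")
def line64_modes(line64):
    return cn.spectrum(line64)


@pytest.fixture(scope="session")
def single_oscillator():
    """N=1 'network': a bare critical Hopf oscillator (A = 0)."""
    return cn.custom_connectivity(np.zeros((1, 1)))


@pytest.fixture()
def zero_state():
    """A zero steady state, for fitting synthetic residual traces."""
    return cn.SteadyState(
        amplitude=np.zeros(1, dtype=complex),
        omega=0.0,
        residual_norm=0.0,
        iterations=0,
        converged=True,
    )


def random_skew(n: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, n))
    return (M - M.T) / 2.0
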