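import numpy as np
import pytest

from phagoshape.shape_model import MaterialParams, solve_equilibrium

_CACHE = {}


def cached_solution(l, kappaG_ratio=-0.2, J0=0.0):
    """Session-wide cache of converged equilibria (continuation reuse)."""
    key = (round(l, 6), round(kappaG_ratio, 6), round(J0, 6))
    if key not in _CACHE:
        _CACHE[key] = solve_equilibrium(
            l, MaterialParams(kappaG_ratio=kappaG_ratio, J0=J0))
    return _CACHE[key]


@pytest.fixture(scope="session")
def sol_l08():
    return cached_solution(0.8)


@pytest.fixture(scope="session")
def sol_l04():
    return cached_solution(0.4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240102)
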