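import numpy as np
import pytest

from prospectwb import (
    DEFAULT_GRID,
    Version,
    flat_background,
    synthetic_coefficients,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def background():
    return flat_background(DEFAULT_GRID)


@pytest.fixture(scope="session")
def coeffs_pd():
    return synthetic_coefficients(Version.PD)


@pytest.fixture(scope="session")
def coeffs_p3():
    return synthetic_coefficients(Version.P3)


@pytest.fixture(scope="session")
def coeffs_p4():
    return synthetic_coefficients(Version.P4)


@pytest.fixture(scope="session")
def coeffs_p5():
    return synthetic_coefficients(Version.P5)


@pytest.fixture
def rng():
    return np.random.default_rng(20180320)
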