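import numpy as np
import pytest

from rbc_rispec import OpticalConstants, QuadratureConfig, build_basis, default_grid


@pytest.fixture(scope="session")
def constants():
    return OpticalConstants.default()


@pytest.fixture(scope="session")
def grid5():
    """Full working range at 5 nm spacing (N=163 > M=84: identifiable)."""
    return default_grid(step=5.0)


@pytest.fixture(scope="session")
def basis5(grid5):
    return build_basis(grid5)


@pytest.fixture(scope="session")
def small_basis():
    """Reduced visible-range basis for fast fitting tests (M=10)."""
    return build_basis(default_grid(420.0, 680.0, 10.0), knot_spacing=40.0)


@pytest.fixture(scope="session")
def fast_quadrature():
    return QuadratureConfig(n_chb=8, n_radius=8)
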