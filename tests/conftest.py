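import numpy as np
import pytest

from fidqdo.qdo import AtomSite, params_from_polarizabilities


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def unit_pair():
    """Two identical oscillators with alpha1 = alpha2 = 1 a.u. at R = 5 bohr."""
    p = params_from_polarizabilities(1.0, 1.0, 0.7)
    a = AtomSite("H", (0.0, 0.0, 0.0), p, alpha1=1.0, alpha2=1.0, label="A")
    b = AtomSite("H", (0.0, 0.0, 5.0), p, alpha1=1.0, alpha2=1.0, label="B")
    return a, b


def random_site(rng, position, label="X"):
    """A randomly parameterized site at a given position (bohr)."""
    alpha1 = float(rng.uniform(0.5, 12.0))
    alpha2 = float(rng.uniform(0.5, 30.0))
    omega = float(rng.uniform(0.3, 1.2))
    p = params_from_polarizabilities(alpha1, alpha2, omega)
    return AtomSite("H", tuple(position), p, alpha1=alpha1, alpha2=alpha2, label=label)
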