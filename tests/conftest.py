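import numpy as np
import pytest

from mtshell import params as P, shell3d


@pytest.fixture(scope="session")
def mt_macro():
    """Microtubule-like moduli (axially stiff, circumferentially soft)."""
    return P.MacroElastic(Ea=0.6e3, Ec=3.0, G=1.5e3, L=200.0, d=8.0, b=500.0)


@pytest.fixture(scope="session")
def small_lattice(mt_macro):
    return shell3d.build_lattice(mt_macro)


@pytest.fixture()
def rng():
    return np.random.default_rng(20180601)
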