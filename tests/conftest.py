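import numpy as np
import pytest

from alchemfe.synthetic import analytic_dimer, HarmonicFamily


@pytest.fixture(scope="session")
def lj_dimer():
    """Analytic Lennard-Jones dimer (ε = σ = 1, reduced units)."""
    return analytic_dimer("LJ", {"epsilon": 1.0, "sigma": 1.0})


@pytest.fixture(scope="session")
def morse_dimer():
    return analytic_dimer("Morse", {"D": 2.0, "a": 2.5, "r_e": 1.1})


@pytest.fixture(scope="session")
def harmonic_family_124():
    """Three harmonic windows with k = (1, 2, 4): exact f_k = ½ ln(k/k0)."""
    return HarmonicFamily(k=(1.0, 2.0, 4.0), d=1, temperature=1.0, kB=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
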