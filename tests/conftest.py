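import numpy as np
import pytest

from friedel_water import GeometryParams, OscillationModel


def brute_force_comb(z, sigma1, g, n_wells, lam=2.9, sigma_cap=2.0):
    """Independent double-loop evaluation of the Gaussian-comb density."""
    rho = np.zeros(len(z))
    for k, zk in enumerate(z):
        for i in list(range(-n_wells, 0)) + list(range(1, n_wells + 1)):
            s = min(sigma1 / g ** (abs(i) - 1), sigma_cap)
            rho[k] += (
                lam
                / (s * np.sqrt(2 * np.pi))
                * np.exp(-((zk - i * lam) ** 2) / (2 * s**2))
            )
    return rho


@pytest.fixture(scope="session")
def nine_nine_geometry():
    """(9,9)-tube-like geometry: d = 1.22 nm, h/d = 0.5."""
    return GeometryParams(d=1.22, h=0.61)


@pytest.fixture(scope="session")
def fine_grid():
    """0.05 A grid over |z| <= 15 A."""
    n = int(round(15.0 / 0.05))
    return np.linspace(-15.0, 15.0, 2 * n + 1)


@pytest.fixture(scope="session")
def reference_model():
    return OscillationModel(sigma1=0.45, decay_ratio=0.85, n_wells=8)
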