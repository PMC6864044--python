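import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from dslox.blood_optics import BloodOpticalCoefficients
from dslox.preprocessing import WindowBank
from dslox.synthetic import NoiseModel, SyntheticDatasetConfig, generate_spectral_dataset


@pytest.fixture(scope="session")
def toy_coeffs():
    """Small hand-checkable coefficient table, 520-640 nm.

    At 560 nm: mu_a_hb = 2, mu_s_hb = 1, mu_a_hbo2 = 4, mu_s_hbo2 = 3;
    all four vary linearly with wavelength, so interpolation values are
    easy to compute by hand.
    """
    lam = np.arange(520.0, 641.0, 10.0)
    t = (lam - 560.0) / 100.0
    return BloodOpticalCoefficients(
        wavelengths=lam,
        mu_a_hb=2.0 + 1.0 * t,
        mu_s_hb=1.0 + 0.5 * t,
        mu_a_hbo2=4.0 - 1.0 * t,
        mu_s_hbo2=3.0 - 0.5 * t,
    )


@pytest.fixture(scope="session")
def bank():
    return WindowBank()


@pytest.fixture(scope="session")
def clean_small_dataset():
    """Noiseless, bias-free small dataset shared across tests."""
    cfg = SyntheticDatasetConfig.small(
        seed=101, n_per_cell=4, noise=NoiseModel.off(),
        bias_coefficients={1: (0.0, 0.0), 2: (0.0, 0.0)},
    )
    return cfg, generate_spectral_dataset(cfg)
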