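import numpy as np
import pytest

import flimsep as fs

GAUSS_FWHM = 2.354820045030949


def gaussian_wrapped(t, center, sigma, period):
    out = np.zeros_like(t)
    for m in (-1, 0, 1):
        out = out + np.exp(-((t - center + m * period) ** 2) / (2 * sigma**2))
    return out


def oracle_decay_pdf(components, optics):
    """Independent forward model: direct O(N^2) circular-convolution sum of a
    bin-center-sampled wrapped Gaussian IRF with wrapped exponentials (no
    FFT, no shared code with the package's pdf)."""
    n = optics.n_time_bins
    t = (np.arange(n) + 0.5) * optics.bin_width
    sigma = optics.irf_fwhm * 1e-3 / GAUSS_FWHM
    irf = gaussian_wrapped(t, optics.irf_offset, sigma, optics.repetition_period)
    irf /= irf.sum()
    mix = np.zeros(n)
    for tau, frac in components:
        w = np.exp(-t / tau)
        mix += frac * w / w.sum()
    out = np.zeros(n)
    idx = np.arange(n)
    for k in range(n):
        out[k] = np.sum(irf * mix[(k - idx) % n])
    return out / out.sum()


def uniform_phantom(tau, size=64, brightness=1.0):
    return fs.Phantom(
        np.ones((size, size), np.int32),
        {1: ((float(tau), 1.0),)},
        {1: float(brightness)},
        {1: "uniform"},
    )


def noiseless_image(components, optics, total=1e6):
    """Single-pixel TCSPC image holding the exact expected histogram."""
    irf = fs.make_irf(optics)
    pdf = fs.wrapped_decay_pdf(components, irf, optics.repetition_period)
    return fs.TCSPCImage((total * pdf).reshape(1, 1, -1), optics)


@pytest.fixture(scope="session")
def optics():
    return fs.OpticsConfig()


@pytest.fixture(scope="session")
def sted_optics():
    return fs.OpticsConfig(pixel_size=20.0, emission_wavelength=700.0)


@pytest.fixture(scope="session")
def reference_img(optics):
    """Homogeneous fluorescein-like calibration acquisition (tau 3.55 ns)."""
    return fs.simulate_confocal_tcspc(uniform_phantom(3.55, 48), optics, 200, seed=901)


@pytest.fixture(scope="session")
def sted_reference_img(sted_optics):
    """Calibration reference matching the STED-scene optics (tau 3.5 ns)."""
    return fs.simulate_confocal_tcspc(
        uniform_phantom(3.5, 32), sted_optics, 500, seed=902
    )


@pytest.fixture(scope="session")
def bead_phantom():
    return fs.make_bead_phantom(
        40.0, 10, 900.0, seed=1, size=224, pixel_size=20.0, tau=3.5
    )


@pytest.fixture(scope="session")
def sted_bead_img(bead_phantom, sted_optics):
    sted = fs.StedConfig(depletion_power_fraction=0.2)
    return fs.simulate_sted_tcspc(bead_phantom, sted_optics, sted, 10000, seed=11)


@pytest.fixture(scope="session")
def confocal_bead_img(bead_phantom, sted_optics):
    return fs.simulate_confocal_tcspc(bead_phantom, sted_optics, 10000, seed=11)
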