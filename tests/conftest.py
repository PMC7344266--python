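import numpy as np
import pytest

from ocuncert import (GIOPConfig, LineHeightChlCoefficients, MULTIBAND_16,
                      NflhBands, Spectrum, SynthConfig, generate_rrs)
from ocuncert.giop import GammaRule


@pytest.fixture(scope="session")
def bands16():
    return MULTIBAND_16


@pytest.fixture(scope="session")
def giop16():
    """GIOP configuration fitting all sixteen bands (for generation)."""
    return GIOPConfig(fit_bands=tuple(MULTIBAND_16.centers))


@pytest.fixture(scope="session")
def lh16():
    """Line-height chlorophyll with the 665 nm red band of the 16-band grid."""
    return LineHeightChlCoefficients(ci_bands=(443.0, 555.0, 665.0))


@pytest.fixture(scope="session")
def nflh16():
    return NflhBands.for_multiband16()


@pytest.fixture(scope="session")
def synthetic_spectra():
    """Thirty realistic synthetic Rrs spectra with their truth table."""
    return generate_rrs(SynthConfig(n=30, seed=42))


@pytest.fixture(scope="session")
def one_spectrum(synthetic_spectra):
    return synthetic_spectra[0][0]


@pytest.fixture
def unit_giop():
    """Degenerate GIOP config with flat unit shapes on three bands.

    aw = bbw = 0.01, aphi* = 1 everywhere, gamma rule constant, so the
    forward model is analytically transparent in unit tests.
    """
    wl = np.array([443.0, 490.0, 555.0])
    flat = lambda v, q: Spectrum(wl, np.full(3, v), q)
    return GIOPConfig(
        fit_bands=(443.0, 490.0, 555.0),
        aphi_star=flat(1.0, "aphi*"),
        aw=flat(0.01, "aw"),
        bbw=flat(0.001, "bbw"),
        gamma_rule=GammaRule(p0=1.0, p1=0.0),
    )
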