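import numpy as np
import pytest

from phasormp.spectral import EmissionSpectrum, WavelengthAxis


@pytest.fixture
def axis_420_740() -> WavelengthAxis:
    """The canonical fixture axis: 420-740 nm at 2.5 nm steps (129 channels)."""
    return WavelengthAxis(start=420.0, step=2.5, count=129)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def gaussian_spectrum(axis: WavelengthAxis, center: float, sigma: float) -> EmissionSpectrum:
    wl = axis.wavelengths
    return EmissionSpectrum(axis, np.exp(-0.5 * ((wl - center) / sigma) ** 2))


def random_spectrum(axis: WavelengthAxis, rng: np.random.Generator) -> EmissionSpectrum:
    vals = rng.random(axis.count)
    if vals.sum() == 0:  # vanishingly unlikely; keep spectra non-empty
        vals[0] = 1.0
    return EmissionSpectrum(axis, vals)


# ---------------------------------------------------------------------------
# Independent oracles, written before the implementations they check.
# They deliberately use plain Python loops / math so they share no code path
# with the package.
# ---------------------------------------------------------------------------

def oracle_phasor(intensities, step: float, span: float, harmonic: int = 1):
    """Direct-summation first-harmonic DFT phasor: plain loop, math module."""
    import math

    total = 0.0
    sx = 0.0
    sy = 0.0
    for k, intensity in enumerate(intensities):
        phase = 2.0 * math.pi * harmonic * (k * step) / span
        total += intensity
        sx += intensity * math.cos(phase)
        sy += intensity * math.sin(phase)
    return sx / total, sy / total, total


def oracle_center_of_mass(wavelengths, intensities) -> float:
    """Brute-force weighted mean."""
    num = 0.0
    den = 0.0
    for wl, intensity in zip(wavelengths, intensities):
        num += wl * intensity
        den += intensity
    return num / den
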