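import numpy as np
import pytest

from dqobm import (
    OpticalConfig,
    compute_dpc_transfer,
    default_source,
    make_pupil,
)


@pytest.fixture(scope="session")
def config64():
    """Small imaging configuration used across the suite (64x64, coarse px)."""
    return OpticalConfig(
        wavelength=0.72, numerical_aperture=0.6, pixel_size=0.2, grid_shape=(64, 64)
    )


@pytest.fixture(scope="session")
def pupil64(config64):
    return make_pupil(config64)


@pytest.fixture(scope="session")
def transfers64(config64, pupil64):
    """Default (horizontal, vertical) transfer-function pair on the 64x64 grid."""
    return tuple(
        compute_dpc_transfer(default_source(config64, axis), pupil64)
        for axis in ("horizontal", "vertical")
    )


@pytest.fixture(scope="session")
def config128():
    return OpticalConfig(
        wavelength=0.72, numerical_aperture=0.6, pixel_size=0.2, grid_shape=(128, 128)
    )


@pytest.fixture(scope="session")
def transfers128(config128):
    pupil = make_pupil(config128)
    return tuple(
        compute_dpc_transfer(default_source(config128, axis), pupil)
        for axis in ("horizontal", "vertical")
    )


def passband_mask(transfers, rel=1e-3):
    """Frequencies where the summed transfer energy exceeds ``rel`` of its peak."""
    energy = transfers[0].values**2 + transfers[1].values**2
    return energy >= rel * energy.max()


def passband_limited_phase(transfers, rng, amplitude=0.3):
    """Random smooth real phase supported on the transfer-function passband."""
    shape = transfers[0].values.shape
    pb = passband_mask(transfers)
    spec = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) * pb
    phi = np.fft.ifft2(spec).real  # discard the anti-Hermitian part -> real field
    phi = np.fft.ifft2(np.fft.fft2(phi) * pb).real
    return phi * (amplitude / np.abs(phi).max())
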