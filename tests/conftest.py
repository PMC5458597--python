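import numpy as np
import pytest

from powderchain.calibrant import load_calibrant
from powderchain.geometry import DetectorSpec, DiffractionGeometry
from powderchain.synthetic import RingRenderSpec, render_calibration_image


@pytest.fixture(scope="session")
def detector512():
    return DetectorSpec(n_slow=512, n_fast=512, pixel_size_slow=0.4, pixel_size_fast=0.4)


@pytest.fixture(scope="session")
def detector64():
    return DetectorSpec(n_slow=64, n_fast=64, pixel_size_slow=0.2, pixel_size_fast=0.2)


@pytest.fixture(scope="session")
def ceria():
    return load_calibrant("CeO2_SRM674b")


@pytest.fixture(scope="session")
def silicon():
    return load_calibrant("Si_SRM640c")


@pytest.fixture(scope="session")
def geometry_mild_tilt(detector512):
    """A realistic powder geometry: small tilts, beam centre slightly off-middle."""
    return DiffractionGeometry(
        distance=300.0,
        beam_centre_fast=250.0,
        beam_centre_slow=262.0,
        tilt_pitch=1.2,
        tilt_yaw=-0.8,
        wavelength=0.7,
        detector=detector512,
    )


@pytest.fixture(scope="session")
def ring_frame_noiseless(geometry_mild_tilt, ceria):
    spec = RingRenderSpec(geometry=geometry_mild_tilt, calibrant=ceria, max_rings=5)
    return render_calibration_image(spec)


@pytest.fixture(scope="session")
def geometry_small(detector64):
    return DiffractionGeometry(
        distance=50.0,
        beam_centre_fast=31.5,
        beam_centre_slow=31.5,
        tilt_pitch=0.0,
        tilt_yaw=0.0,
        wavelength=1.0,
        detector=detector64,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
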