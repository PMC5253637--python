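import numpy as np
import pytest

from toccsl.params import ImagingParams, PhotophysicsParams, ProtocolTiming, Rect, SceneParams


@pytest.fixture(scope="session")
def photo():
    return PhotophysicsParams()  # lognormal mean 100 counts, CV 0.3, p = 1


@pytest.fixture(scope="session")
def imaging():
    return ImagingParams()


@pytest.fixture(scope="session")
def monomer_samples(photo):
    """Large seeded monomer-brightness calibration sample."""
    rng = np.random.default_rng(1234)
    return photo.draw_monomer_brightness(rng, 5000)


@pytest.fixture(scope="session")
def rho1(monomer_samples):
    from toccsl.mixture import estimate_monomer_pdf

    return estimate_monomer_pdf(monomer_samples, n_max=5)


@pytest.fixture()
def small_scene():
    return SceneParams(
        true_alpha=(0.6, 0.4),
        density=0.3,
        diffusion_coeff=0.5,
        mobile_fraction=0.8,
        field_size=(12.0, 12.0),
    )


@pytest.fixture()
def small_timing():
    return ProtocolTiming(roi=Rect(3.0, 3.0, 9.0, 9.0), t_recovery=3000.0)
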