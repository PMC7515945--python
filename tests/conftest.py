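import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def quiet_camera():
    """Small noiseless camera for deterministic expectation checks."""
    from climargin.phantom import CameraModel
    return CameraModel(sensor_shape=(64, 64), read_noise_sigma=0.0,
                       dark_offset=0.0, gamma_strike_rate_per_s=0.0,
                       defective_pixels=(), shot_noise=False,
                       counts_per_radiance_s=1e-4)


@pytest.fixture
def small_camera():
    """Small camera with the full noise model."""
    from climargin.phantom import CameraModel
    return CameraModel(sensor_shape=(64, 64), defective_pixels=((10, 40),),
                       counts_per_radiance_s=1e-4)
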