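import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spec():
    """A quick sharp phantom with zero clinician margin."""
    from edemaseg.phantom import PhantomSpec

    return PhantomSpec(
        shape=(12, 48, 48),
        pixel_spacing=(1.0, 1.0),
        slice_thickness=1.0,
        edema_center=(6, 24, 24),
        edema_semi_axes_mm=(4.0, 8.0, 7.0),
        gts_margin_mm=0.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    from edemaseg.phantom import generate_phantom

    return generate_phantom(small_spec)
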