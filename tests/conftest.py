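import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def crawl_sim():
    """One in-memory forward crawl with ground truth, shared across tests."""
    from wormtrace.synth import simulate_crawl

    return simulate_crawl(out_dir=None, duration_s=10.0, fps=5, seed=11)


@pytest.fixture(scope="session")
def rendered_worm():
    """A rendered sinusoidal worm frame with ground truth."""
    from wormtrace.synth import WormPose, render_worm

    pose = WormPose(amplitude_um=80.0, wavelength_um=1100.0, phase=0.9, heading_rad=0.4)
    image, truth = render_worm(pose, seed=5, noise_sigma=5.0)
    return pose, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
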