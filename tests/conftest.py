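import numpy as np
import pytest

from octava import channel_grid_phantom, network_phantom
from octava.pipeline import FrangiConfig, RunConfig, analyze_image


def run_phantom(image, median_kernel=1, twig_size_px=3, **overrides):
    """Analyze a phantom with the plain pipeline (no vesselness step:
    the synthetic channels/vessels are uniform-intensity, which is the
    regime where enhancement is unnecessary and may distort widths)."""
    cfg = RunConfig(pixel_size_um=image.pixel_size_um, median_kernel=median_kernel,
                    frangi=FrangiConfig(enabled=False), twig_size_px=twig_size_px,
                    **overrides)
    return analyze_image(image, cfg)


@pytest.fixture(scope="session")
def grid_phantom():
    return channel_grid_phantom()


@pytest.fixture(scope="session")
def grid_run(grid_phantom):
    image, _ = grid_phantom
    return run_phantom(image)


@pytest.fixture(scope="session")
def netfree_phantom():
    """Noise-free network phantom (exact-recovery regime)."""
    return network_phantom(seed=1, noise_level=0.0, intensity_variation=0.0)


@pytest.fixture(scope="session")
def netfree_run(netfree_phantom):
    image, _ = netfree_phantom
    return run_phantom(image)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Speckled phantom at SNR 5 with along-vessel intensity variation,
    without junctions (per-vessel parameter-recovery regime)."""
    return network_phantom(seed=3, n_connectors=0, noise_level=0.2,
                           intensity_variation=0.3)


@pytest.fixture(scope="session")
def noisy_run(noisy_phantom):
    image, _ = noisy_phantom
    return run_phantom(image, median_kernel=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
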