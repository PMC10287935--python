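import numpy as np
import pytest

from clusterscope.synth import GroundTruthSpot, SceneSpec, render_spot_stack


def random_spot(rng, shape=(15, 40, 40), tilted=True):
    """One random in-domain spot with a comfortably nonzero tilted background."""
    nz, ny, nx = shape
    bg = (rng.uniform(50, 150),
          rng.uniform(0.2, 1.0) * rng.choice([-1, 1]),
          rng.uniform(0.2, 1.0) * rng.choice([-1, 1]),
          rng.uniform(0.2, 1.0) * rng.choice([-1, 1])) if tilted else (0.0,) * 4
    return GroundTruthSpot(
        x0=rng.uniform(10, nx - 10), y0=rng.uniform(10, ny - 10),
        z0=rng.uniform(4, nz - 5),
        sigma_xy=rng.uniform(1.3, 2.0), sigma_z=rng.uniform(0.9, 1.4),
        total_intensity=rng.uniform(2000, 10000), background=bg)


@pytest.fixture
def single_spot_stack():
    """Noiseless rendered spot with known parameters."""
    truth = GroundTruthSpot(x0=20.3, y0=17.6, z0=7.2, sigma_xy=1.7,
                            sigma_z=1.1, total_intensity=5000.0,
                            background=(100.0, 0.3, -0.2, 0.5))
    scene = SceneSpec(shape=(15, 40, 40), seed=0)
    stack, table = render_spot_stack([truth], scene)
    return stack, truth
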