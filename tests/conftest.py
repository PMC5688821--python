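import numpy as np
import pytest

from fragaria3d.synthgen import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170)


@pytest.fixture(scope="session")
def clean_scene():
    """One deterministic zero-noise scene with its ground truth."""
    spec = SceneSpec(seed=42, noise_sd_mm=0.0, colour_noise_sd=0.0)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def small_spec():
    """A lighter scene spec for tests that rebuild scenes repeatedly."""
    return SceneSpec(
        seed=11,
        n_holder_points=3000,
        n_body_points=8000,
        n_calyx_points=1000,
        n_achenes=60,
        noise_sd_mm=0.0,
        colour_noise_sd=0.0,
    )


def random_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
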