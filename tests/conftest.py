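import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from calfish.registration import SimilarityTransform
from calfish.synthetic import SynthConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def blob_scene(shape, transform, n_blobs=40, scene_seed=1,
               noise_rng=None, snr=5.0):
    """Analytic Gaussian-blob scene rendered in the frame given by
    ``transform`` (pixel q shows the fixed-frame scene at transform(q)),
    so a (fixed, moving) image pair shares no interpolation error."""
    r = np.random.default_rng(scene_seed)
    h, w = shape
    cx = r.uniform(15, w - 15, n_blobs)
    cy = r.uniform(15, h - 15, n_blobs)
    amp = r.uniform(0.5, 2.0, n_blobs)
    sig = r.uniform(4, 12, n_blobs)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pf = transform.apply_points(pts)
    img = np.zeros(h * w)
    for a, s, x0, y0 in zip(amp, sig, cx, cy):
        img += a * np.exp(-(((pf[:, 0] - x0) ** 2 + (pf[:, 1] - y0) ** 2) / (2 * s * s)))
    img = img.reshape(shape)
    if noise_rng is not None:
        img = img + noise_rng.normal(0, img.std() / snr, img.shape)
    return img


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_cells=60, widefield_shape=(256, 256),
                       confocal_shape=(256, 256), n_planes=5, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)
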