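import numpy as np
import pytest

from dermatone import (
    ClusterModelConfig,
    RegionSpec,
    SceneSpec,
    default_palette,
    render_scene,
    srgb_to_lab,
)


@pytest.fixture(scope="session")
def palette():
    return default_palette()


@pytest.fixture(scope="session")
def two_blobs():
    """Two tight, far-separated Gaussian blobs in LAB with known labels."""
    rng = np.random.default_rng(42)
    a = rng.normal(loc=[30.0, 5.0, 10.0], scale=1.0, size=(60, 3))
    b = rng.normal(loc=[70.0, 15.0, 30.0], scale=1.0, size=(60, 3))
    pixels = np.vstack([a, b])
    labels = np.array([0] * 60 + [1] * 60)
    return pixels, labels


@pytest.fixture(scope="session")
def two_region_lab(palette):
    """75/25 two-region scene (FST III / FST IV) at sensor noise sigma=2."""
    spec = SceneSpec(
        regions=[RegionSpec(3, 0.75), RegionSpec(4, 0.25)],
        height=128,
        width=128,
        lighting_gradient=0.0,
        noise_sigma=2.0,
        seed=11,
    )
    rgb, truth, fractions = render_scene(spec, palette)
    return srgb_to_lab(rgb), truth, fractions


@pytest.fixture
def kmeans_cfg():
    def make(k=2, seed=0, **params):
        return ClusterModelConfig(model_name="kmeans", n_clusters=k, seed=seed, params=params)

    return make
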