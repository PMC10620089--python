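import numpy as np
import pytest

from lplnet.synthetic_data import (
    ClusterSequenceConfig,
    LatentVideoConfig,
    SlowSignalConfig,
    gen_cluster_pairs,
    gen_latent_video,
    gen_slow_signal,
)


@pytest.fixture(scope="session")
def cluster_config():
    return ClusterSequenceConfig(sigma_y=0.5, n_pairs=10_000, seed=11)


@pytest.fixture(scope="session")
def cluster_batch(cluster_config):
    return gen_cluster_pairs(cluster_config)


@pytest.fixture(scope="session")
def slow_trace():
    return gen_slow_signal(SlowSignalConfig(period=3.0, seed=7), duration=39.0)


@pytest.fixture(scope="session")
def small_video():
    return gen_latent_video(LatentVideoConfig(n_frames=17 * 40, image_size=24, seed=5))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
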