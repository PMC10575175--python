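import numpy as np
import pytest

import skelact as sk


@pytest.fixture(scope="session")
def topology():
    return sk.default_topology()


@pytest.fixture(scope="session")
def tiny_dataset(topology):
    """2 subjects x 3 actions x 2 reps, short clips, noiseless."""
    cfg = sk.GeneratorConfig(
        num_subjects=2, num_actions=3, num_repetitions=2,
        frames_per_clip=16, noise_std=0.0, seed=7,
    )
    return sk.generate_dataset(cfg, topology)


@pytest.fixture(scope="session")
def desk_heatmap_config():
    return sk.HeatmapConfig(out_height=24, out_width=24, num_frames_out=8)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
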