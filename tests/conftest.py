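import numpy as np
import pytest

from stridekit.synthgait import SyntheticGaitConfig, generate_walk


@pytest.fixture(scope="session")
def small_walk():
    """A short noisy walk shared by read-only tests."""
    cfg = SyntheticGaitConfig(n_strides=10, seed=42)
    seq, events, lengths = generate_walk(cfg)
    return seq, events, lengths


@pytest.fixture()
def walk_files(tmp_path):
    """Synthetic walk written to disk in the package's own formats."""
    from stridekit.synthgait import write_walk

    cfg = SyntheticGaitConfig(n_strides=8, seed=3)
    imu, events, truth = write_walk(tmp_path, cfg)
    return imu, events, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
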