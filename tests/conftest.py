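import numpy as np
import pytest

import miranet as mn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained network for fast structural tests."""
    cfg = mn.ModelConfig(depth=2, base_channels=8, channel_growth=2,
                         n_atoms=4, mlp_hidden=16)
    return mn.MiraNet(cfg, seed=3)


@pytest.fixture(scope="session")
def experiment_report():
    """The desk-scale unified-vs-single-task experiment, run once per session.

    Fixed seed: the comparison is a frozen fixture (3 tasks, 64x64 phantoms,
    200/25/25 splits per task, small model).
    """
    return mn.run_comparison_experiment(mn.ExperimentConfig(seed=0))
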