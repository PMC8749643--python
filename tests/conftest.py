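import numpy as np
import pytest

from oxispec import model as M
from oxispec import preprocess as pp
from oxispec import simulator as sim


@pytest.fixture(scope="session")
def sim_cfg():
    """Default simulator configuration (full 12-channel bank)."""
    return sim.default_config(seed=0)


@pytest.fixture(scope="session")
def clean_cfg():
    """Simulator without sensor read noise: pure Beer-Lambert physics."""
    return sim.default_config(seed=0).with_(read_noise_counts=0.0)


@pytest.fixture(scope="session")
def label_frames(sim_cfg):
    """One frame per SpO2 label from a single simulated session."""
    rng = np.random.default_rng(11)
    return [sim.simulate_frame(lab, sim_cfg, rng) for lab in pp.DEFAULT_LABELS]


@pytest.fixture(scope="session")
def second_dataset(label_frames):
    """Second-region training dataset at the study's preferred 2 % noise."""
    return pp.build_dataset(
        label_frames, pp.REGIONS["SECOND"], noise_ratio=0.02, n_rows_per_label=100, seed=5
    )


@pytest.fixture(scope="session")
def trained_second_model(second_dataset):
    """A small converged classifier on the second region, reused across tests."""
    cfg = M.best_reported_config(epochs=60, seed=2)
    net = M.build_model(cfg, 6, 10)
    return M.train(net, second_dataset, cfg)
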