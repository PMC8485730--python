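import numpy as np
import pytest

from stimscope.sim import SimConfig, simulate_session


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(fov_px=(32, 32), n_cells=3, cell_radius_px=(2.0, 3.0),
                     frame_rate_hz=20.0, seed=7)


@pytest.fixture(scope="session")
def small_awake_session():
    """A 64x64, 2000-frame awake session with stimulation blocks, shared by
    extraction and analysis tests (generation is the slow part)."""
    cfg = SimConfig(fov_px=(64, 64), n_cells=15, cell_radius_px=(3.0, 5.0),
                    seed=3)
    movie, truth = simulate_session(cfg, "awake", 2000, block_s=20)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def anesthetized_session():
    """An anesthetized session: quiescent baseline, stimulation-recruited
    activity, with compressed inter-train gaps to keep it short."""
    cfg = SimConfig(fov_px=(64, 64), n_cells=15, cell_radius_px=(3.0, 5.0),
                    baseline_rate_hz=0.0, seed=5)
    movie, truth = simulate_session(cfg, "anesthetized", 3000, gap_s=5.0)
    return cfg, movie, truth
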