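import numpy as np
import pandas as pd
import pytest

import gazepipe as gp
from gazepipe.geometry import TrialLayout, side_by_side_aois


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def cascade_layout():
    return TrialLayout(
        aois=side_by_side_aois(173, 173),
        fixation_duration_ms=2000.0,
        stim_start_ms=2000.0,
    )


def _samples(t, x, y):
    return pd.DataFrame({"t_ms": t, "x_px": x, "y_px": y, "live_feed": False})


@pytest.fixture
def make_samples():
    return _samples


@pytest.fixture(scope="session")
def small_cascade():
    cfg = gp.SimulationConfig(n_participants=8, n_trials=6, seed=301)
    return gp.simulate_cascade_study(cfg)


@pytest.fixture(scope="session")
def small_novelty():
    cfg = gp.SimulationConfig(n_participants=8, n_trials=6, seed=302)
    return gp.simulate_novelty_study(cfg)


@pytest.fixture(scope="session")
def small_vwp():
    cfg = gp.SimulationConfig(n_participants=6, n_trials=4, seed=303)
    return gp.simulate_vwp_study(cfg)


@pytest.fixture(scope="session")
def clean_cascade():
    """Noise-free, offset-free, fully deterministic looking behaviour."""
    cfg = gp.SimulationConfig(
        n_participants=5,
        n_trials=12,  # enough that an all-same-choice run is vanishingly rare
        seed=304,
        noise_sd_px=0.0,
        off_aoi_rate=0.0,
        offset=gp.OffsetSpec(0.0, 0.0),
        preference={"p_final": 1.0, "participant_sd": 0.0, "ramp_ms": 0.0},
    )
    return gp.simulate_cascade_study(cfg)
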