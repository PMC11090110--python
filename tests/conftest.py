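import numpy as np
import pandas as pd
import pytest

from smflux import pipeline, simulate


@pytest.fixture(scope="session")
def apo_trajectories():
    """Three-state trajectory ensemble at the resting-state parameters."""
    cfg = simulate.TrajectorySimConfig(
        n_traj=1000, n_frames=21, dt=0.1, states=pipeline.APO_STATES,
        transition_rates=pipeline._occupancy_generator(pipeline.APO_STATES, 0.5),
        loc_sigma=0.02, bleach_rate=0.0, seed=20240601,
    )
    return simulate.simulate_trajectories(cfg), cfg


@pytest.fixture(scope="session")
def monomer_traces():
    """Single-fluorophore bleaching traces at the monomer reference conditions."""
    cfg = simulate.TraceSimConfig(
        n_traces=300, n_frames=200, frame_dt=0.5, brightness_mean=4.4,
        brightness_sd=0.88, bleach_tau=14.7, noise_sd=1.0, seed=42,
    )
    traces, truth = simulate.simulate_traces(cfg)
    return traces, truth, cfg


@pytest.fixture()
def single_spot_movie():
    """A noiseless rendered movie with one bright static spot and its truth."""
    truth = pd.DataFrame(
        {"frame": [0], "id": [0], "x_um": [2.5], "y_um": [3.1], "I": [1000.0]}
    )
    stack = simulate.render_movie(truth, psf_sigma=0.13, shape=(40, 40))
    return stack, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
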