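import logging

import numpy as np
import pytest

import photonpath as pp

logging.getLogger("photonpath").setLevel(logging.ERROR)


def state_occupancy(truth: pp.GroundTruthPath) -> dict[int, float]:
    occ: dict[int, float] = {}
    for start, end, s in truth.segments:
        occ[s] = occ.get(s, 0.0) + (end - start)
    return occ


def simulate_of_kind(scheme, duration, start_seed, required_states, min_occupancy=1.0):
    """First simulated trajectory (from start_seed upward) whose ground
    truth occupies every required state for at least min_occupancy seconds
    — i.e. a realization that is genuinely 'of the kind' its scheme names."""
    seed = start_seed
    while True:
        cfg = pp.SimulationConfig(scheme=scheme, duration=duration, seed=seed)
        traj, truth = pp.simulate_trajectory(cfg)
        occ = state_occupancy(truth)
        if all(occ.get(s, 0.0) >= min_occupancy for s in required_states):
            return traj, truth, seed
        seed += 1


@pytest.fixture(scope="session")
def worked_example_sim():
    """A glass-like single-step bleach trace: ~1625 photons/s emitting state
    photobleaching to ~649 photons/s background, both states well occupied."""
    traj, truth, _ = simulate_of_kind(
        pp.two_state_bleach_scheme(649.0, 1625.0, 6.0), 16.0, 11, (0, 1)
    )
    return traj, truth


@pytest.fixture(scope="session")
def blink_sim():
    """A ZMW-like blink trace with solid occupancy of background and both
    emitting states (>= 2 s each)."""
    traj, truth, _ = simulate_of_kind(
        pp.three_state_blink_scheme(), 20.0, 21, (0, 1, 2), min_occupancy=2.0
    )
    return traj, truth
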