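"""Shared fixtures: trained controllers are expensive, so they are built
once per session at the scaled-down desk budget and reused across tests."""

import numpy as np
import pytest

from neuroctrl.environments import ParticleEnv, ParticleTaskConfig
from neuroctrl.experiments import (
    eval_start_grid,
    make_lqg_oracle,
    particle_costs,
    train_particle_direct,
)
from neuroctrl.rnn_controller import RNNController


@pytest.fixture(scope="session")
def trained_particle_net():
    """Particle-task RNN trained with the direct backend (2 epochs x 1000
    trajectories, seed 0) — the criterion-scale budget."""
    return train_particle_direct(seed=0)


@pytest.fixture(scope="session")
def eval_starts():
    """100 held-out start states, disjoint from the training grid draws."""
    return eval_start_grid(100, seed=777)


@pytest.fixture(scope="session")
def lqr_baseline_costs(eval_starts):
    """Analytic optimal-control cost on the held-out starts (full state)."""
    lqg = make_lqg_oracle(ParticleTaskConfig(obs_mode="full_state"))
    return particle_costs(lqg, eval_starts)


@pytest.fixture(scope="session")
def particle_env():
    return ParticleEnv(ParticleTaskConfig())
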