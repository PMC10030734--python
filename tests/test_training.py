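"""Training backends: guards, bookkeeping, reproducibility, and the
stateful-filtering advantage. Statistical performance claims live in the
acceptance suite."""

import numpy as np
import pytest

from neuroctrl.dynamics import NoiseSpec, ObservationModel
from neuroctrl.environments import ParticleEnv, ParticleTaskConfig, PendulumEnv
from neuroctrl.experiments import make_lqg_oracle, particle_costs, eval_start_grid
from neuroctrl.linear_control import LqrCost
from neuroctrl.rnn_controller import RNNController, init_rnn, particle_rnn
from neuroctrl.training import (
    DirectTrainConfig,
    OracleDataset,
    OracleTrainConfig,
    RLConfig,
    UnsupportedEnvironmentError,
    collect_oracle_dataset,
    train_direct,
    train_oracle,
    train_rl,
)

COST = LqrCost.identity(2, 1)


def tiny_direct_cfg(**kw):
    base = dict(epochs=1, trajectories_per_epoch=50, batch_size=10, episode_len=30, seed=0)
    base.update(kw)
    return DirectTrainConfig(**base)


class TestMethodGuards:
    """Method selection mirrors the environment-assumption table: direct
    needs a differentiable (linear, known) plant, oracle a linear known
    plant, RL only the step/reset contract."""

    def test_direct_rejects_nonlinear_env(self):
        env = PendulumEnv()
        rnn = init_rnn([8], env.observation_dim, 1, seed=0)
        with pytest.raises(UnsupportedEnvironmentError):
            train_direct(env, rnn, COST, tiny_direct_cfg())

    def test_oracle_rejects_nonlinear_env(self):
        env = PendulumEnv()
        with pytest.raises(UnsupportedEnvironmentError):
            collect_oracle_dataset(make_lqg_oracle(), env, 2, seed=0)

    def test_rl_accepts_any_step_reset_env(self):
        env = PendulumEnv()
        rnn = init_rnn([8], env.observation_dim, 1, seed=0)
        trained, curve = train_rl(env, rnn, RLConfig(episodes=8, episodes_per_update=4,
                                                     epochs_per_update=2, seed=0))
        assert len(curve.values) == 2

    def test_rl_rejects_non_env(self):
        with pytest.raises(UnsupportedEnvironmentError):
            train_rl(object(), init_rnn([4], 1, 1, 0), RLConfig(episodes=4))


class TestDirect:
    def test_zero_epochs_returns_params_unchanged(self):
        env = ParticleEnv(ParticleTaskConfig(obs_mode="full_state"))
        rnn = particle_rnn(0)
        trained, curve = train_direct(env, rnn, COST, tiny_direct_cfg(epochs=0))
        assert (trained.layers[0].A_rec == rnn.layers[0].A_rec).all()
        assert (trained.readout.C_out == rnn.readout.C_out).all()
        assert curve.values == []

    def test_same_seed_bitwise_reproducible(self):
        env = ParticleEnv(ParticleTaskConfig(obs_mode="full_state"))
        a, ca = train_direct(env, particle_rnn(0), COST, tiny_direct_cfg())
        b, cb = train_direct(env, particle_rnn(0), COST, tiny_direct_cfg())
        assert (a.layers[0].A_rec == b.layers[0].A_rec).all()
        assert ca.values == cb.values

    def test_loss_improves(self):
        env = ParticleEnv(ParticleTaskConfig(obs_mode="full_state"))
        cfg = tiny_direct_cfg(epochs=2, trajectories_per_epoch=200, episode_len=100)
        _, curve = train_direct(env, particle_rnn(0), COST, cfg)
        assert np.mean(curve.values[-5:]) < 0.2 * np.mean(curve.values[:5])

    def test_environment_parameters_frozen(self):
        env = ParticleEnv(ParticleTaskConfig(obs_mode="full_state"))
        A_before = env.model.A.copy()
        train_direct(env, particle_rnn(0), COST, tiny_direct_cfg())
        assert (env.model.A == A_before).all()

    def test_stateful_beats_memoryless_under_noise(self):
        """Recurrence lets the controller filter noisy position-only
        input; a feedforward net of the same width trained identically
        does worse (the implicit-Kalman-filter effect)."""
        env = ParticleEnv(ParticleTaskConfig(obs_mode="noisy_position"))
        starts = eval_start_grid(50, seed=321)
        obsm = ObservationModel.noisy_position(2, 0.1)
        cfg_kw = dict(epochs=1, trajectories_per_epoch=600, batch_size=10, seed=0)
        stateful_costs, memoryless_costs = [], []
        for seed in range(5):
            rnn = init_rnn([50], 1, 1, seed, output_gain=3.0)
            tr, _ = train_direct(env, rnn, COST, DirectTrainConfig(**cfg_kw))
            stateful_costs.append(
                particle_costs(RNNController(tr), starts, obs_model=obsm, seed=1).mean())

            ff = init_rnn([50], 1, 1, seed, output_gain=3.0)
            ff.layers[0].A_rec[:] = 0.0
            tr_ff, _ = train_direct(env, ff, COST,
                                    DirectTrainConfig(freeze=("L0.A",), **cfg_kw))
            assert (tr_ff.layers[0].A_rec == 0.0).all()
            memoryless_costs.append(
                particle_costs(RNNController(tr_ff), starts, obs_model=obsm, seed=1).mean())
        assert np.median(stateful_costs) < np.median(memoryless_costs)


@pytest.fixture(scope="module")
def small_dataset():
    env = ParticleEnv(ParticleTaskConfig(obs_mode="noisy_position"))
    return collect_oracle_dataset(make_lqg_oracle(env.config), env, 40, seed=0)


class TestOracle:

    def test_dataset_bookkeeping(self, small_dataset):
        assert small_dataset.inputs.shape == (40, 100, 1)
        assert small_dataset.labels.shape == (40, 100, 1)
        assert np.isfinite(small_dataset.labels).all()
        # oracle controls stay within the gain it needs on the start grid
        assert np.abs(small_dataset.labels).max() < 1 + np.sqrt(3) + 1.0

    def test_labels_replay_consistency(self):
        """Replaying recorded controls open loop in a noiseless clone
        reproduces the oracle's closed-loop trajectory."""
        from neuroctrl.dynamics import episode_rng, rollout
        from neuroctrl.environments import double_integrator_model

        env = ParticleEnv(ParticleTaskConfig(obs_mode="full_state"))
        lqg = make_lqg_oracle(env.config)
        data = collect_oracle_dataset(lqg, env, 1, seed=3)
        model = double_integrator_model(NoiseSpec.zero(2, 1))
        x0 = env._grid[episode_rng(3, 0).integers(len(env._grid))]
        x = x0.copy()
        states = [x.copy()]
        for t in range(99):
            x = x + 0.1 * model.drift(x, data.labels[0, t])
            states.append(x.copy())
        # with full-state noiseless obs the recorded y equals the true state
        assert np.allclose(states, data.inputs[0], atol=1e-10)

    def test_degenerate_zero_regression(self):
        data = OracleDataset(np.zeros((8, 20, 1)), np.zeros((8, 20, 1)))
        rnn = init_rnn([10], 1, 1, seed=0)
        trained, _ = train_oracle(rnn, data, OracleTrainConfig(epochs=100, batch_size=8, seed=0))
        from neuroctrl.rnn_controller import RNNState, rnn_step
        s = RNNState.zeros(trained)
        outs = []
        for _ in range(20):
            s, o = rnn_step(s, np.zeros(1), trained)
            outs.append(o[0])
        assert np.abs(outs).max() < 0.1

    def test_empty_dataset_raises(self):
        with pytest.raises(ValueError):
            train_oracle(init_rnn([4], 1, 1, 0),
                         OracleDataset(np.zeros((0, 5, 1)), np.zeros((0, 5, 1))),
                         OracleTrainConfig())

    def test_heldout_mse_decreases(self, small_dataset):
        rnn = init_rnn([50], 1, 1, seed=0, output_gain=3.0)
        _, curve = train_oracle(rnn, small_dataset, OracleTrainConfig(epochs=3, seed=0))
        assert curve.eval_values[-1] < curve.eval_values[0]

    def test_same_seed_bitwise_reproducible(self, small_dataset):
        cfg = OracleTrainConfig(epochs=1, seed=5)
        a, ca = train_oracle(init_rnn([10], 1, 1, 0), small_dataset, cfg)
        b, cb = train_oracle(init_rnn([10], 1, 1, 0), small_dataset, cfg)
        assert (a.layers[0].A_rec == b.layers[0].A_rec).all()
        assert ca.values == cb.values


class TestRL:
    def test_curve_and_param_change(self):
        env = ParticleEnv(ParticleTaskConfig(obs_mode="noisy_position"))
        rnn = particle_rnn(0, obs_dim=1)
        cfg = RLConfig(episodes=32, episodes_per_update=8, epochs_per_update=2, seed=0)
        trained, curve = train_rl(env, rnn, cfg)
        assert len(curve.values) == 4
        assert not np.allclose(trained.readout.C_out, rnn.readout.C_out)

    def test_first_epoch_ratio_is_one(self):
        """On-policy sanity: before any update the importance ratio is 1,
        so a single update with zero learning rate leaves params fixed."""
        env = ParticleEnv(ParticleTaskConfig(obs_mode="noisy_position"))
        rnn = particle_rnn(0, obs_dim=1)
        cfg = RLConfig(episodes=8, episodes_per_update=8, epochs_per_update=1,
                       learning_rate=1e-30, seed=0)
        trained, _ = train_rl(env, rnn, cfg)
        assert np.allclose(trained.layers[0].A_rec, rnn.layers[0].A_rec, atol=1e-12)
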