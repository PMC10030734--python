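"""LQR synthesis, Kalman filtering, and the LQG composition."""

import numpy as np
import pytest

from neuroctrl.dynamics import NoiseSpec, ObservationModel, Trajectory, episode_rng, rollout
from neuroctrl.environments import double_integrator_model
from neuroctrl.experiments import make_lqg_oracle, particle_costs, eval_start_grid
from neuroctrl.environments import ParticleTaskConfig
from neuroctrl.linear_control import (
    LinearSystem,
    LqgController,
    LqrCost,
    SynthesisError,
    kalman_gain,
    lqr_cost_of_trajectory,
    lqr_gain,
)


def riccati_fixed_point(A, B, Q, R, dt=5e-3, iters=200_000, tol=1e-13):
    """Independent oracle: integrate the continuous Riccati ODE to its
    fixed point P satisfying A'P + PA - P B R^-1 B' P + Q = 0."""
    n = A.shape[0]
    P = np.eye(n)
    Rinv = np.linalg.inv(R)
    for _ in range(iters):
        dP = A.T @ P + P @ A - P @ B @ Rinv @ B.T @ P + Q
        P = P + dt * dP
        if np.abs(dP).max() < tol:
            break
    return P


def random_stabilizable_system(rng, n):
    A = rng.standard_normal((n, n))
    A = A - (np.max(np.linalg.eigvals(A).real) + 0.3) * np.eye(n)  # shift stable
    B = rng.standard_normal((n, 1))
    return LinearSystem(A, B, np.eye(n), NoiseSpec.zero(n, n))


class TestLqrGain:
    def test_double_integrator_closed_form(self):
        """Hand-solved Riccati: P = [[sqrt3,1],[1,sqrt3]], K = [1, sqrt3]."""
        sys_ = LinearSystem([[0, 1], [0, 0]], [[0], [1]], [[1, 0]], NoiseSpec.zero(2, 1))
        K = lqr_gain(sys_, LqrCost.identity(2, 1))
        assert np.allclose(K, [[1.0, np.sqrt(3.0)]], atol=1e-8)

    def test_stable_plant_zero_state_cost(self):
        sys_ = LinearSystem(-np.eye(2), [[1], [0]], np.eye(2), NoiseSpec.zero(2, 2))
        K = lqr_gain(sys_, LqrCost(np.zeros((2, 2)), np.eye(1)))
        assert np.allclose(K, 0.0)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_riccati_ode_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 5))
        sys_ = random_stabilizable_system(rng, n)
        Q = np.eye(n)
        R = np.eye(1)
        K = lqr_gain(sys_, LqrCost(Q, R))
        P = riccati_fixed_point(sys_.A, sys_.B, Q, R)
        K_oracle = np.linalg.solve(R, sys_.B.T @ P)
        assert np.allclose(K, K_oracle, atol=1e-6)

    def test_unstabilizable_system_raises(self):
        # unstable mode decoupled from the input
        sys_ = LinearSystem([[1, 0], [0, -1]], [[0], [1]], np.eye(2), NoiseSpec.zero(2, 2))
        with pytest.raises(SynthesisError):
            lqr_gain(sys_, LqrCost.identity(2, 1))

    def test_closed_loop_is_stable(self):
        rng = np.random.default_rng(5)
        sys_ = random_stabilizable_system(rng, 4)
        K = lqr_gain(sys_, LqrCost.identity(4, 1))
        eig = np.linalg.eigvals(sys_.A - sys_.B @ K)
        assert eig.real.max() < 0

    def test_gain_is_first_order_optimal(self, eval_starts):
        """Random perturbations of the optimal gain never lower the mean
        closed-loop cost on a fixed noiseless ensemble. Simulated at a
        fine step (dt = 0.01) so the continuous-time optimum is optimal
        up to discretization error below the second-order penalty."""
        model = double_integrator_model(NoiseSpec.zero(2, 1))
        obs = ObservationModel.full_state(2)
        cost = LqrCost.identity(2, 1)
        K = lqr_gain(LinearSystem(model.A, model.B, [[1, 0]], NoiseSpec.zero(2, 1)), cost)
        starts = eval_starts[:10]
        rng = np.random.default_rng(0)

        def mean_j(gain):
            ctrl = lambda y: -(gain @ y)
            return np.mean([
                lqr_cost_of_trajectory(
                    rollout(model, ctrl, obs, x0, 1000, 0.01, episode_rng(0, i)), cost)
                for i, x0 in enumerate(starts)
            ])

        j_opt = mean_j(K)
        for _ in range(20):
            delta = rng.standard_normal(K.shape)
            delta *= 0.05 / np.linalg.norm(delta)
            assert mean_j(K + delta) >= j_opt - 1e-9


class TestKalman:
    def test_scalar_random_walk_gain(self):
        """x' = x + w, y = x + eps, unit variances: steady gain (sqrt5-1)/2."""
        sys_ = LinearSystem([[0.0]], [[0.0]], [[1.0]],
                            NoiseSpec([[1.0]], [[1.0]]))
        # dt = 1 makes the discretized plant the unit random walk
        L = kalman_gain(sys_, dt=1.0)
        assert L[0, 0] == pytest.approx((np.sqrt(5) - 1) / 2, abs=1e-10)

    def test_undetectable_raises(self):
        sys_ = LinearSystem([[1, 0], [0, 1]], [[1], [1]], [[1, 0]],
                            NoiseSpec(np.eye(2), [[1.0]]))
        with pytest.raises(SynthesisError):
            kalman_gain(sys_, dt=0.1)

    def test_velocity_estimate_converges(self):
        """Position-only filtering reconstructs the unobserved velocity
        better than the trivial zero-velocity guess."""
        lqg = make_lqg_oracle(ParticleTaskConfig(obs_mode="noisy_position"))
        model = double_integrator_model(NoiseSpec.zero(2, 1))
        obs = ObservationModel.noisy_position(2, 0.1)
        errs, zero_errs = [], []
        for i in range(20):
            rng = episode_rng(9, i)
            x = np.array([np.cos(i), np.sin(i)])
            lqg.reset()
            v_true, v_est = [], []
            for t in range(100):
                y = obs.obs_matrix @ x + obs.noise.sample_obs(rng)
                u = lqg(y)
                v_true.append(x[1]); v_est.append(lqg.x_hat[1])
                x = x + 0.1 * model.drift(x, u)
            v_true, v_est = np.array(v_true), np.array(v_est)
            errs.append(np.sqrt(np.mean((v_true[50:] - v_est[50:]) ** 2)))
            zero_errs.append(np.sqrt(np.mean(v_true[50:] ** 2)))
        assert np.mean(errs) < np.mean(zero_errs)


class TestLqgController:
    def test_requires_reset(self):
        lqg = make_lqg_oracle()
        lqg._x_hat = None
        with pytest.raises(RuntimeError):
            lqg(np.zeros(1))

    def test_zero_observations_zero_controls(self):
        lqg = make_lqg_oracle()
        lqg.reset()
        for _ in range(10):
            assert np.allclose(lqg(np.zeros(1)), 0.0)

    def test_separation_principle(self):
        """With exact full observation the filter passes the state through
        and LQG reproduces plain LQR state feedback."""
        cfg = ParticleTaskConfig(obs_mode="full_state")
        lqg = make_lqg_oracle(cfg)
        model = double_integrator_model(NoiseSpec.zero(2, 1))
        obs = ObservationModel.full_state(2)
        K = lqg.K
        traj_lqg = rollout(model, lqg, obs, np.array([1.0, -0.5]), 100, 0.1,
                           episode_rng(0, 0))
        traj_lqr = rollout(model, lambda y: -(K @ y), obs, np.array([1.0, -0.5]),
                           100, 0.1, episode_rng(0, 0))
        assert np.allclose(traj_lqg.controls, traj_lqr.controls, atol=1e-5)

    def test_noisy_position_lqg_beats_uncontrolled(self, eval_starts):
        """Paired comparison: the LQG loop has strictly lower quadratic
        cost than leaving the particle uncontrolled, per episode."""
        lqg = make_lqg_oracle(ParticleTaskConfig(obs_mode="noisy_position"))
        obsm = ObservationModel.noisy_position(2, 0.1)
        starts = eval_starts
        j_lqg = particle_costs(lqg, starts, obs_model=obsm, seed=4)
        j_zero = particle_costs(lambda y: np.zeros(1), starts, obs_model=obsm, seed=4)
        assert (j_lqg < j_zero).mean() > 0.8
        assert j_lqg.mean() < 0.2 * j_zero.mean()

    def test_json_roundtrip(self, tmp_path):
        lqg = make_lqg_oracle()
        lqg.to_json(tmp_path / "lqg.json")
        back = LqgController.from_json(tmp_path / "lqg.json")
        assert np.allclose(back.K, lqg.K) and np.allclose(back.L, lqg.L)
        back.reset()
        lqg.reset()
        y = np.array([0.37])
        assert np.allclose(back(y), lqg(y))


class TestCostOfTrajectory:
    def test_single_step(self):
        traj = Trajectory(np.array([0.0]), np.array([[1.0, 0.0]]),
                          np.array([[0.0]]), np.array([[1.0]]), np.zeros(1))
        assert lqr_cost_of_trajectory(traj, LqrCost.identity(2, 1)) == 1.0

    def test_zero_trajectory(self):
        traj = Trajectory(np.arange(5) * 0.1, np.zeros((5, 2)),
                          np.zeros((5, 1)), np.zeros((5, 1)), np.zeros(5))
        assert lqr_cost_of_trajectory(traj, LqrCost.identity(2, 1)) == 0.0

    def test_empty_raises(self):
        traj = Trajectory(np.zeros(0), np.zeros((0, 2)), np.zeros((0, 1)),
                          np.zeros((0, 1)), np.zeros(0))
        with pytest.raises(ValueError):
            lqr_cost_of_trajectory(traj, LqrCost.identity(2, 1))
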