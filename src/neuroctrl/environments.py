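"""Benchmark plants: stochastic double integrator and inverted pendulum.

The double integrator models a unit-mass particle on a line whose
acceleration equals the control force; the task is to drive it to rest at
the origin. The pendulum is a cart–pole with the pole's angular dynamics
theta_dd = (g/l) sin(theta); the control force accelerates the cart. Note
that in this plant the control does not enter the angular acceleration, so
the pole angle is an autonomous unstable subsystem — a deliberate property
of the model equations used here, which differs from the fully coupled
MuJoCo-style cartpole.

Both plants also expose a gym-style ``reset``/``step`` interface so generic
RL drivers can attach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .dynamics import NoiseSpec, ObservationModel, SdeModel, euler_maruyama_step, observe

__all__ = [
    "Outcome",
    "EpisodeStatus",
    "ParticleTaskConfig",
    "PendulumTaskConfig",
    "double_integrator_model",
    "pendulum_model",
    "particle_status",
    "particle_reward",
    "pendulum_status_and_reward",
    "ParticleEnv",
    "PendulumEnv",
    "particle_start_grid",
]

DEG = np.pi / 180.0


class Outcome(str, Enum):
    RUNNING = "running"
    SUCCESS = "success"
    FAILURE = "failure"
    TIMEOUT = "timeout"


@dataclass(frozen=True)
class EpisodeStatus:
    outcome: Outcome
    step: int

    @property
    def terminal(self) -> bool:
        return self.outcome is not Outcome.RUNNING


@dataclass(frozen=True)
class ParticleTaskConfig:
    """Particle stabilization task.

    Success when the state norm drops below `success_radius`; failure if
    that has not happened after `max_steps`. Observation is either the full
    state or a noisy position-only readout with variance `obs_variance`.
    """

    success_radius: float = 1e-3
    max_steps: int = 100
    obs_mode: str = "full_state"  # or "noisy_position"
    obs_variance: float = 0.1
    dt: float = 0.1
    process_var: float = 0.0
    grid_extent: float = 1.0
    grid_side: int = 100

    def __post_init__(self):
        if self.success_radius <= 0:
            raise ValueError("success_radius must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.obs_mode not in ("full_state", "noisy_position"):
            raise ValueError(f"unknown obs_mode {self.obs_mode!r}")

    def observation_model(self) -> ObservationModel:
        if self.obs_mode == "full_state":
            return ObservationModel.full_state(2)
        return ObservationModel.noisy_position(2, self.obs_variance)


@dataclass(frozen=True)
class PendulumTaskConfig:
    """Pole balancing task: +1 reward per step the pole stays within
    `angle_limit` of upright; episodes time out after `max_steps`."""

    gravity: float = 9.81
    pole_length: float = 0.6
    angle_limit: float = 11.0 * DEG
    max_steps: int = 1000
    obs_mode: str = "position_and_angle"  # or "full_state"
    dt: float = 0.02
    process_var: float = 0.0
    init_scale: float = 0.01

    def __post_init__(self):
        if not (0.0 < self.angle_limit < np.pi / 2):
            raise ValueError("angle_limit must be in (0, pi/2)")
        if self.pole_length <= 0:
            raise ValueError("pole_length must be positive")
        if self.obs_mode not in ("full_state", "position_and_angle"):
            raise ValueError(f"unknown obs_mode {self.obs_mode!r}")

    def observation_model(self) -> ObservationModel:
        if self.obs_mode == "full_state":
            return ObservationModel.full_state(4)
        # cart position and pole angle, but not their velocities
        C = np.zeros((2, 4))
        C[0, 0] = 1.0
        C[1, 2] = 1.0
        return ObservationModel(C, NoiseSpec.zero(4, 2))


# ---------------------------------------------------------------------------
# plant constructors


def double_integrator_model(noise: NoiseSpec) -> SdeModel:
    """Stochastic double integrator: state (q, qdot), drift (qdot, u)."""
    if noise.process_cov.shape[0] != 2:
        raise ValueError("double integrator needs 2-dim process noise")
    A = np.array([[0.0, 1.0], [0.0, 0.0]])
    B = np.array([[0.0], [1.0]])

    def drift(x: np.ndarray, u: np.ndarray) -> np.ndarray:
        return np.array([x[1], u[0]])

    return SdeModel(drift=drift, noise=noise, state_dim=2, control_dim=1,
                    name="double_integrator", A=A, B=B)


def pendulum_model(config: PendulumTaskConfig, noise: NoiseSpec) -> SdeModel:
    """Cart–pole plant with state (x, xdot, theta, thetadot).

    Drift: (xdot, u, thetadot, (g/l) sin theta). The control force enters
    the cart acceleration only; the angle subsystem is autonomous.
    """
    g_over_l = config.gravity / config.pole_length

    def drift(x: np.ndarray, u: np.ndarray) -> np.ndarray:
        return np.array([x[1], u[0], x[3], g_over_l * np.sin(x[2])])

    return SdeModel(drift=drift, noise=noise, state_dim=4, control_dim=1, name="pendulum")


# ---------------------------------------------------------------------------
# termination and reward


def particle_status(state: np.ndarray, step: int, config: ParticleTaskConfig) -> EpisodeStatus:
    """Success below the radius; failure at the step budget; running otherwise."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if np.linalg.norm(state) < config.success_radius:
        return EpisodeStatus(Outcome.SUCCESS, step)
    if step >= config.max_steps:
        return EpisodeStatus(Outcome.FAILURE, step)
    return EpisodeStatus(Outcome.RUNNING, step)


def particle_reward(
    state: np.ndarray,
    control: np.ndarray,
    status: EpisodeStatus,
    Q: np.ndarray,
    R: np.ndarray,
    dt: float,
) -> float:
    """Negative quadratic regulator loss per step, plus +1 on success."""
    x = np.atleast_1d(state)
    u = np.atleast_1d(control)
    r = -float(x @ Q @ x + u @ R @ u) * dt
    if status.outcome is Outcome.SUCCESS:
        r += 1.0
    return r


def pendulum_status_and_reward(
    state: np.ndarray, step: int, config: PendulumTaskConfig
) -> tuple[EpisodeStatus, float]:
    """+1 per surviving step; failure once |theta| exceeds the angle limit;
    timeout (counted as success) at the step budget."""
    theta = state[2]
    if abs(theta) > config.angle_limit:
        return EpisodeStatus(Outcome.FAILURE, step), 0.0
    if step + 1 >= config.max_steps:
        return EpisodeStatus(Outcome.TIMEOUT, step), 1.0
    return EpisodeStatus(Outcome.RUNNING, step), 1.0


# ---------------------------------------------------------------------------
# start-state samplers


def particle_start_grid(config: ParticleTaskConfig) -> np.ndarray:
    """Uniform grid of (position, velocity) start states over the square
    [-extent, extent]^2, flattened to (grid_side^2, 2)."""
    axis = np.linspace(-config.grid_extent, config.grid_extent, config.grid_side)
    q, qd = np.meshgrid(axis, axis, indexing="ij")
    return np.stack([q.ravel(), qd.ravel()], axis=1)


# ---------------------------------------------------------------------------
# gym-style wrappers


class _GymEnvBase:
    """Minimal gym-style contract: reset(seed) -> obs; step(u) ->
    (obs, reward, terminated, truncated, info)."""

    observation_dim: int
    control_dim: int = 1

    def reset(self, seed: int | None = None) -> np.ndarray:
        raise NotImplementedError

    def step(self, control) -> tuple[np.ndarray, float, bool, bool, dict]:
        raise NotImplementedError


class ParticleEnv(_GymEnvBase):
    """Particle stabilization episode driver with the shaped reward
    (negative quadratic loss, +1 bonus on reaching the success radius)."""

    def __init__(self, config: ParticleTaskConfig | None = None,
                 Q: np.ndarray | None = None, R: np.ndarray | None = None):
        self.config = config or ParticleTaskConfig()
        self.Q = np.eye(2) if Q is None else np.asarray(Q, dtype=float)
        self.R = np.eye(1) if R is None else np.atleast_2d(np.asarray(R, dtype=float))
        noise = NoiseSpec(self.config.process_var * np.eye(2), np.zeros((1, 1)))
        self.model = double_integrator_model(noise)
        self.obs_model = self.config.observation_model()
        self.observation_dim = self.obs_model.obs_dim
        self._grid = particle_start_grid(self.config)
        self._rng: np.random.Generator | None = None
        self.state: np.ndarray | None = None
        self._step_count = 0

    def reset(self, seed: int | None = None) -> np.ndarray:
        if seed is not None or self._rng is None:
            self._rng = np.random.default_rng(seed)
        self.state = self._grid[self._rng.integers(len(self._grid))].copy()
        self._step_count = 0
        return observe(self.state, self.obs_model, self._rng)

    def step(self, control) -> tuple[np.ndarray, float, bool, bool, dict]:
        assert self.state is not None, "call reset() first"
        u = np.atleast_1d(np.asarray(control, dtype=float))
        self.state = euler_maruyama_step(self.state, u, self.model, self.config.dt, self._rng)
        self._step_count += 1
        status = particle_status(self.state, self._step_count, self.config)
        reward = particle_reward(self.state, u, status, self.Q, self.R, self.config.dt)
        obs = observe(self.state, self.obs_model, self._rng)
        terminated = status.outcome is Outcome.SUCCESS
        truncated = status.outcome is Outcome.FAILURE
        return obs, reward, terminated, truncated, {"status": status}


class PendulumEnv(_GymEnvBase):
    """Pole balancing episode driver; reward counts surviving steps."""

    def __init__(self, config: PendulumTaskConfig | None = None):
        self.config = config or PendulumTaskConfig()
        noise = NoiseSpec(self.config.process_var * np.eye(4), np.zeros((1, 1)))
        self.model = pendulum_model(self.config, noise)
        self.obs_model = self.config.observation_model()
        self.observation_dim = self.obs_model.obs_dim
        self._rng: np.random.Generator | None = None
        self.state: np.ndarray | None = None
        self._step_count = 0

    def reset(self, seed: int | None = None) -> np.ndarray:
        if seed is not None or self._rng is None:
            self._rng = np.random.default_rng(seed)
        s = self.config.init_scale
        self.state = self._rng.uniform(-s, s, size=4)
        self._step_count = 0
        return observe(self.state, self.obs_model, self._rng)

    def step(self, control) -> tuple[np.ndarray, float, bool, bool, dict]:
        assert self.state is not None, "call reset() first"
        u = np.atleast_1d(np.asarray(control, dtype=float))
        self.state = euler_maruyama_step(self.state, u, self.model, self.config.dt, self._rng)
        status, reward = pendulum_status_and_reward(self.state, self._step_count, self.config)
        self._step_count += 1
        obs = observe(self.state, self.obs_model, self._rng)
        terminated = status.outcome is Outcome.FAILURE
        truncated = status.outcome is Outcome.TIMEOUT
        return obs, reward, terminated, truncated, {"status": status}
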