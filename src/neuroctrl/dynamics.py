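"""Stochastic dynamical-system core: SDE models, Euler–Maruyama stepping,
noisy partial observation, and closed-loop episode rollouts.

The plant is a controlled SDE ``dx = mu(x, u) dt + sigma dw`` with constant
diffusion, discretized by the Euler–Maruyama scheme
``x_{t+1} = x_t + dt * mu(x_t, u_t) + dw_t`` where ``dw_t ~ N(0, dt * S)``
and ``S = Sigma_p Sigma_p^T`` is the process-noise covariance. Observations
are a linear readout corrupted by Gaussian noise, ``y = C x + eps``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "NoiseSpec",
    "SdeModel",
    "ObservationModel",
    "Trajectory",
    "DivergenceError",
    "euler_maruyama_step",
    "observe",
    "rollout",
]


class DivergenceError(RuntimeError):
    """Raised when a simulated state becomes non-finite."""


def _check_cov(mat: np.ndarray, name: str) -> np.ndarray:
    mat = np.atleast_2d(np.asarray(mat, dtype=np.float64))
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() < -1e-10:
        raise ValueError(f"{name} must be positive semi-definite")
    return mat


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Factor F with F F^T = cov, valid for singular PSD matrices."""
    w, v = np.linalg.eigh(cov)
    return v * np.sqrt(np.clip(w, 0.0, None))


@dataclass(frozen=True)
class NoiseSpec:
    """Process and observation noise covariances.

    `process_cov` is S = Sigma_p Sigma_p^T in state units squared per unit
    time; `obs_cov` is Sigma_o in observation units squared. Zero matrices
    give the deterministic limit.
    """

    process_cov: np.ndarray
    obs_cov: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "process_cov", _check_cov(self.process_cov, "process_cov"))
        object.__setattr__(self, "obs_cov", _check_cov(self.obs_cov, "obs_cov"))
        object.__setattr__(self, "_proc_factor", _psd_factor(self.process_cov))
        object.__setattr__(self, "_obs_factor", _psd_factor(self.obs_cov))

    @classmethod
    def zero(cls, state_dim: int, obs_dim: int | None = None) -> "NoiseSpec":
        obs_dim = state_dim if obs_dim is None else obs_dim
        return cls(np.zeros((state_dim, state_dim)), np.zeros((obs_dim, obs_dim)))

    @classmethod
    def isotropic(cls, state_dim: int, process_var: float, obs_dim: int, obs_var: float) -> "NoiseSpec":
        return cls(process_var * np.eye(state_dim), obs_var * np.eye(obs_dim))

    def sample_process(self, dt: float, rng: np.random.Generator) -> np.ndarray:
        """Draw dw ~ N(0, dt * S)."""
        z = rng.standard_normal(self.process_cov.shape[0])
        return np.sqrt(dt) * (getattr(self, "_proc_factor") @ z)

    def sample_obs(self, rng: np.random.Generator) -> np.ndarray:
        factor = getattr(self, "_obs_factor")
        z = rng.standard_normal(self.obs_cov.shape[0])
        return factor @ z


@dataclass
class SdeModel:
    """Controlled SDE with drift `mu(x, u)` and constant diffusion.

    If the drift is linear, `A` and `B` hold the state and input matrices so
    analytic controller synthesis can read them; they are None otherwise.
    """

    drift: Callable[[np.ndarray, np.ndarray], np.ndarray]
    noise: NoiseSpec
    state_dim: int
    control_dim: int
    name: str = "sde"
    A: np.ndarray | None = None
    B: np.ndarray | None = None

    @property
    def is_linear(self) -> bool:
        return self.A is not None and self.B is not None


@dataclass
class ObservationModel:
    """Linear observation y = C x + eps with eps ~ N(0, Sigma_o)."""

    obs_matrix: np.ndarray
    noise: NoiseSpec

    def __post_init__(self):
        self.obs_matrix = np.atleast_2d(np.asarray(self.obs_matrix, dtype=np.float64))
        if self.noise.obs_cov.shape[0] != self.obs_matrix.shape[0]:
            raise ValueError("obs_cov dimension must match observation dimension")

    @property
    def obs_dim(self) -> int:
        return self.obs_matrix.shape[0]

    @classmethod
    def full_state(cls, state_dim: int) -> "ObservationModel":
        return cls(np.eye(state_dim), NoiseSpec.zero(state_dim, state_dim))

    @classmethod
    def noisy_position(cls, state_dim: int, variance: float) -> "ObservationModel":
        """Observe only the first state coordinate, with Gaussian noise."""
        C = np.zeros((1, state_dim))
        C[0, 0] = 1.0
        return cls(C, NoiseSpec(np.zeros((state_dim, state_dim)), [[variance]]))


@dataclass
class Trajectory:
    """One episode: aligned sequences of times, states, controls,
    observations and per-step costs (or rewards)."""

    times: np.ndarray
    states: np.ndarray
    controls: np.ndarray
    observations: np.ndarray
    step_costs: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.times)
        for name in ("states", "controls", "observations", "step_costs"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != times length {n}")
        if n >= 2:
            dts = np.diff(self.times)
            if dts.min() <= 0 or not np.allclose(dts, dts[0], rtol=1e-9):
                raise ValueError("times must be strictly increasing with constant spacing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self) > 1 else 0.0

    def to_csv(self, path: str | Path) -> None:
        """Write the episode as CSV plus a JSON metadata sidecar."""
        path = Path(path)
        cols: dict[str, np.ndarray] = {"t": self.times}
        for i in range(self.states.shape[1]):
            cols[f"x_{i}"] = self.states[:, i]
        for i in range(self.controls.shape[1]):
            cols[f"u_{i}"] = self.controls[:, i]
        for i in range(self.observations.shape[1]):
            cols[f"y_{i}"] = self.observations[:, i]
        cols["cost"] = self.step_costs
        pd.DataFrame(cols).to_csv(path, index=False)
        path.with_suffix(".json").write_text(json.dumps(self.meta, indent=2, default=float))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}

        def block(prefix: str) -> np.ndarray:
            names = sorted(
                (c for c in df.columns if c.startswith(prefix)),
                key=lambda c: int(c[len(prefix):]),
            )
            return df[names].to_numpy()

        return cls(
            times=df["t"].to_numpy(),
            states=block("x_"),
            controls=block("u_"),
            observations=block("y_"),
            step_costs=df["cost"].to_numpy(),
            meta=meta,
        )


def _as_vec(x, dim: int, name: str) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    if x.shape != (dim,):
        raise ValueError(f"{name} has shape {x.shape}, expected ({dim},)")
    return x


def euler_maruyama_step(
    state: np.ndarray,
    control: np.ndarray,
    model: SdeModel,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One Euler–Maruyama step: x + dt*mu(x, u) + dw, dw ~ N(0, dt*S).

    With a zero process covariance this is exactly the forward-Euler step.
    Raises :class:`DivergenceError` when the state stops being finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    state = _as_vec(state, model.state_dim, "state")
    control = _as_vec(control, model.control_dim, "control")
    if not np.all(np.isfinite(state)):
        raise DivergenceError(f"non-finite state entering step: {state}")
    nxt = state + dt * _as_vec(model.drift(state, control), model.state_dim, "drift output")
    if np.any(model.noise.process_cov):
        nxt = nxt + model.noise.sample_process(dt, rng)
    if not np.all(np.isfinite(nxt)):
        raise DivergenceError(f"state diverged to {nxt}")
    return nxt


def observe(state: np.ndarray, obs: ObservationModel, rng: np.random.Generator) -> np.ndarray:
    """Sample y = C x + eps, eps ~ N(0, Sigma_o)."""
    state = _as_vec(state, obs.obs_matrix.shape[1], "state")
    y = obs.obs_matrix @ state
    if np.any(obs.noise.obs_cov):
        y = y + obs.noise.sample_obs(rng)
    return y


def rollout(
    model: SdeModel,
    controller: Callable[[np.ndarray], np.ndarray],
    obs: ObservationModel,
    x0: np.ndarray,
    n_steps: int,
    dt: float,
    rng: np.random.Generator,
    cost_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
    stop_fn: Callable[[np.ndarray, int], bool] | None = None,
) -> Trajectory:
    """Run one closed-loop episode: observe -> control -> step, repeated.

    The controller may be stateful (an RNN); if it has a ``reset`` method it
    is called at episode start. ``cost_fn(state, control)`` fills the
    per-step cost channel (zeros if omitted). ``stop_fn(state, step)`` may
    terminate the episode early; the trajectory then ends at that step.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if hasattr(controller, "reset"):
        controller.reset()
    x = _as_vec(x0, model.state_dim, "x0")
    times, states, controls, observations, costs = [], [], [], [], []
    for t in range(n_steps):
        y = observe(x, obs, rng)
        u = _as_vec(controller(y), model.control_dim, "control")
        times.append(t * dt)
        states.append(x.copy())
        controls.append(u)
        observations.append(y)
        costs.append(float(cost_fn(x, u)) if cost_fn is not None else 0.0)
        if stop_fn is not None and stop_fn(x, t):
            break
        x = euler_maruyama_step(x, u, model, dt, rng)
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        controls=np.asarray(controls),
        observations=np.asarray(observations),
        step_costs=np.asarray(costs),
        meta={"dt": dt, "model": model.name, "n_steps": len(times)},
    )


def episode_rng(root_seed: int, episode_index: int) -> np.random.Generator:
    """Independent, reproducible per-episode generator derived from a root seed."""
    return np.random.default_rng([int(root_seed), int(episode_index)])
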