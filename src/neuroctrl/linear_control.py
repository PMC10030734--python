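"""Analytic optimal control for known linear plants.

Provides the continuous-time LQR gain (via the algebraic Riccati equation),
a steady-state Kalman filter for the time-discretized system, and their
composition — LQG — which serves both as a performance baseline and as an
oracle teacher for supervised distillation into RNN controllers.

Sign convention: gains are stored positive-definite-Riccati style and the
feedback applies ``u = -K x``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

from .dynamics import NoiseSpec, Trajectory

__all__ = [
    "LinearSystem",
    "LqrCost",
    "LqgController",
    "SynthesisError",
    "lqr_gain",
    "kalman_gain",
    "lqr_cost_of_trajectory",
]


class SynthesisError(ValueError):
    """Raised when a system fails the stabilizability/detectability checks."""


def _is_stabilizable(A: np.ndarray, B: np.ndarray) -> bool:
    """PBH test: every unstable mode must be reachable."""
    n = A.shape[0]
    for lam in np.linalg.eigvals(A):
        if lam.real >= -1e-10:
            M = np.hstack([A - lam * np.eye(n), B])
            if np.linalg.matrix_rank(M, tol=1e-9) < n:
                return False
    return True


@dataclass
class LinearSystem:
    """Continuous-time linear plant dx = (A x + B u) dt + noise, y = C x + eps."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    noise: NoiseSpec

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.atleast_2d(np.asarray(self.B, dtype=float))
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        n = self.A.shape[0]
        if self.A.shape != (n, n) or self.B.shape[0] != n or self.C.shape[1] != n:
            raise ValueError("inconsistent system matrix dimensions")

    @property
    def state_dim(self) -> int:
        return self.A.shape[0]


@dataclass
class LqrCost:
    """Quadratic cost J = integral of x'Qx + u'Ru."""

    Q: np.ndarray
    R: np.ndarray

    def __post_init__(self):
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        if np.linalg.eigvalsh(self.Q).min() < -1e-10:
            raise ValueError("Q must be positive semi-definite")
        if np.linalg.eigvalsh(self.R).min() <= 0:
            raise ValueError("R must be positive definite")

    @classmethod
    def identity(cls, state_dim: int, control_dim: int) -> "LqrCost":
        return cls(np.eye(state_dim), np.eye(control_dim))


def lqr_gain(system: LinearSystem, cost: LqrCost) -> np.ndarray:
    """Solve the continuous algebraic Riccati equation and return K with
    the feedback convention u = -K x."""
    if not _is_stabilizable(system.A, system.B):
        raise SynthesisError("(A, B) is not stabilizable")
    if not np.any(cost.Q) and np.all(np.linalg.eigvals(system.A).real < 0):
        # stable plant, no state cost: doing nothing is optimal
        return np.zeros((system.B.shape[1], system.state_dim))
    P = scipy.linalg.solve_continuous_are(system.A, system.B, cost.Q, cost.R)
    return np.linalg.solve(cost.R, system.B.T @ P)


def discretize(system: LinearSystem, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact zero-order-hold discretization (Ad, Bd) of the linear plant."""
    n, m = system.state_dim, system.B.shape[1]
    M = np.zeros((n + m, n + m))
    M[:n, :n] = system.A
    M[:n, n:] = system.B
    E = scipy.linalg.expm(M * dt)
    return E[:n, :n], E[:n, n:]


def kalman_gain(system: LinearSystem, dt: float,
                design_process_cov: np.ndarray | None = None) -> np.ndarray:
    """Steady-state Kalman gain for the dt-discretized system.

    The filter Riccati equation uses the plant's process covariance unless
    `design_process_cov` overrides it (a nonzero design value keeps the
    steady-state gain nonzero even for a deterministic plant).
    """
    if not _is_stabilizable(system.A.T, system.C.T):
        raise SynthesisError("(A, C) is not detectable")
    Ro = system.noise.obs_cov
    if np.linalg.eigvalsh(Ro).min() <= 0:
        raise SynthesisError("observation covariance must be positive definite")
    S = system.noise.process_cov if design_process_cov is None else np.asarray(design_process_cov)
    Ad, _ = discretize(system, dt)
    Qd = dt * S
    P = scipy.linalg.solve_discrete_are(Ad.T, system.C.T, Qd, Ro)
    return P @ system.C.T @ np.linalg.inv(system.C @ P @ system.C.T + Ro)


def lqr_cost_of_trajectory(traj: Trajectory, cost: LqrCost) -> float:
    """Rectangle-rule quadrature of the quadratic cost along a trajectory."""
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    dt = traj.dt if len(traj) > 1 else 1.0
    x, u = traj.states, traj.controls
    return float(np.einsum("ti,ij,tj->", x, cost.Q, x) +
                 np.einsum("ti,ij,tj->", u, cost.R, u)) * dt


class LqgController:
    """LQR state feedback on a steady-state Kalman filter estimate.

    Stateful across an episode: ``reset()`` zeroes the estimate, then each
    call maps one observation to one control via predict (with the previous
    control) and innovation-correct with gain L, returning u = -K x_hat.
    """

    def __init__(self, system: LinearSystem, cost: LqrCost, dt: float,
                 design_process_cov: np.ndarray | None = None):
        self.K = lqr_gain(system, cost)
        self.L = kalman_gain(system, dt, design_process_cov=design_process_cov)
        self.Ad, self.Bd = discretize(system, dt)
        self.C = system.C
        self.dt = dt
        self._x_hat: np.ndarray | None = None
        self._u_prev: np.ndarray | None = None

    def reset(self, x_hat0: np.ndarray | None = None) -> None:
        n = self.Ad.shape[0]
        self._x_hat = np.zeros(n) if x_hat0 is None else np.asarray(x_hat0, dtype=float).copy()
        self._u_prev = np.zeros(self.Bd.shape[1])

    @property
    def x_hat(self) -> np.ndarray:
        if self._x_hat is None:
            raise RuntimeError("controller used before reset()")
        return self._x_hat

    def __call__(self, observation: np.ndarray) -> np.ndarray:
        if self._x_hat is None:
            raise RuntimeError("controller used before reset()")
        y = np.atleast_1d(np.asarray(observation, dtype=float))
        x_pred = self.Ad @ self._x_hat + self.Bd @ self._u_prev
        self._x_hat = x_pred + self.L @ (y - self.C @ x_pred)
        u = -self.K @ self._x_hat
        self._u_prev = u
        return u

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "K": self.K.tolist(), "L": self.L.tolist(),
            "Ad": self.Ad.tolist(), "Bd": self.Bd.tolist(),
            "C": self.C.tolist(), "dt": self.dt,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LqgController":
        d = json.loads(Path(path).read_text())
        obj = cls.__new__(cls)
        obj.K = np.asarray(d["K"]); obj.L = np.asarray(d["L"])
        obj.Ad = np.asarray(d["Ad"]); obj.Bd = np.asarray(d["Bd"])
        obj.C = np.asarray(d["C"]); obj.dt = d["dt"]
        obj._x_hat = None; obj._u_prev = None
        return obj
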