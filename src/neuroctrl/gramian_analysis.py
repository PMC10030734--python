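"""Empirical controllability and observability Gramians.

The Gramians are estimated data-driven, from the system's response to
stereotyped inputs, so the same recipe applies to linear plants (where it
can be checked against the Lyapunov-equation solution) and to the
nonlinear closed-loop neural system:

* controllability — apply a discrete unit impulse (amplitude s/dt for one
  tick) on each input channel, subtract the unforced reference trajectory,
  and accumulate the outer products of the state responses over the
  horizon;
* observability — perturb the initial state along each direction by +/- s,
  record the output responses, and accumulate inner products of the
  symmetrized response pairs.

Both average over impulse scales and signs and normalize by s^2, making
the estimate exact (up to discretization) for linear systems. The number
of leading eigenvectors needed to explain 90% of the eigenvalue mass — the
variance dimension — lower-bounds the number of stimulation or recording
electrodes a prosthesis needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dynamics import SdeModel
from .rnn_controller import RNNParams, RNNState, rnn_step

__all__ = [
    "GramianResult",
    "LinearDiscreteSystem",
    "ClosedLoopAssociationSystem",
    "empirical_controllability_gramian",
    "empirical_observability_gramian",
    "variance_dimension",
    "electrode_lower_bound",
]


@dataclass
class GramianResult:
    """Symmetric PSD Gramian estimate with its eigenspectrum."""

    gramian: np.ndarray
    eigenvalues: np.ndarray  # descending
    threshold: float
    variance_dim: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "eigenvalues": self.eigenvalues.tolist(),
            "threshold": self.threshold,
            "variance_dim": self.variance_dim,
        }, indent=2))
        np.savez(Path(path).with_suffix(".npz"), gramian=self.gramian)


def variance_dimension(g: GramianResult | np.ndarray, threshold: float) -> int:
    """Smallest k whose top-k eigenvalues explain `threshold` of the total."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    eig = g.eigenvalues if isinstance(g, GramianResult) else np.sort(np.asarray(g))[::-1]
    total = eig.sum()
    if total <= 0:
        raise ValueError("all-zero Gramian has no variance dimension")
    frac = np.cumsum(eig) / total
    return int(np.searchsorted(frac, threshold - 1e-12) + 1)


def _finalize(W: np.ndarray, threshold: float) -> GramianResult:
    W = 0.5 * (W + W.T)  # enforce symmetry
    eig = np.sort(np.linalg.eigvalsh(W))[::-1]
    return GramianResult(W, eig, threshold, variance_dimension(eig, threshold))


# ---------------------------------------------------------------------------
# stepper protocols


class LinearDiscreteSystem:
    """Discrete linear stepper x' = Ad x + Bd u, y = C x, reference 0.

    `from_continuous` builds the exact-exponential discretization of a
    continuous (A, B, C) triple, the form the Lyapunov oracle applies to.
    """

    def __init__(self, Ad: np.ndarray, Bd: np.ndarray, C: np.ndarray):
        self.Ad = np.atleast_2d(Ad)
        self.Bd = np.atleast_2d(Bd)
        self.C = np.atleast_2d(C)
        self.n_inputs = self.Bd.shape[1]
        self.n_states = self.Ad.shape[0]

    @classmethod
    def from_continuous(cls, A: np.ndarray, B: np.ndarray, C: np.ndarray,
                        dt: float) -> "LinearDiscreteSystem":
        import scipy.linalg
        A = np.atleast_2d(A); B = np.atleast_2d(B)
        n, m = A.shape[0], B.shape[1]
        M = np.zeros((n + m, n + m))
        M[:n, :n] = A; M[:n, n:] = B
        E = scipy.linalg.expm(M * dt)
        return cls(E[:n, :n], E[:n, n:], C)

    def reference(self):
        return np.zeros(self.n_states)

    def step(self, state, u=None):
        x = self.Ad @ state
        if u is not None:
            x = x + self.Bd @ u
        return x

    def state_vec(self, state):
        return state

    def readout(self, state):
        return self.C @ state

    def perturb(self, state, delta):
        return state + delta


class ClosedLoopAssociationSystem:
    """The trained neural system in closed loop with its (deterministic)
    environment, probed at the association layer.

    Inputs are stimulation currents injected one per association neuron
    (identity B_EN); the state of interest and the recorded output are the
    concatenated association rates. One tick equals one network step, so
    dt = 1 in units of the network time constant. The reference state is
    the origin-stabilized operating point reached after `settle` ticks.
    """

    def __init__(self, rnn: RNNParams, model: SdeModel, obs_matrix: np.ndarray,
                 dt: float, settle: int = 200):
        self.rnn = rnn
        self.model = model
        self.obs_matrix = np.atleast_2d(obs_matrix)
        self.dt = dt
        self.settle = settle
        self.n_inputs = rnn.n_association
        self.n_states = rnn.n_association
        self._layer_slices = []
        start = 0
        for layer in rnn.layers:
            self._layer_slices.append(slice(start, start + layer.size))
            start += layer.size

    def reference(self):
        state = (np.zeros(self.model.state_dim), RNNState.zeros(self.rnn))
        for _ in range(self.settle):
            state = self.step(state)
        return state

    def step(self, state, u=None):
        x_env, rnn_state = state
        y = self.obs_matrix @ x_env
        injections = None
        if u is not None and np.any(u):
            injections = [u[sl] for sl in self._layer_slices]
        rnn_state, control = rnn_step(rnn_state, y, self.rnn, injections=injections)
        x_env = x_env + self.dt * self.model.drift(x_env, control)
        return (x_env, rnn_state)

    def state_vec(self, state):
        return np.concatenate(state[1].rates)

    def readout(self, state):
        return np.concatenate(state[1].rates)

    def perturb(self, state, delta):
        x_env, rnn_state = state
        rates = np.concatenate(rnn_state.rates) + delta
        rates = np.clip(rates, -1 + 1e-9, 1 - 1e-9)  # rates live in (-1, 1)
        new = RNNState([rates[sl].copy() for sl in self._layer_slices])
        return (x_env, new)


# ---------------------------------------------------------------------------
# Gramian estimators


def empirical_controllability_gramian(system, impulse_scales=(0.5, 1.0),
                                      horizon: int = 50, dt: float = 1.0,
                                      threshold: float = 0.9) -> GramianResult:
    """Average outer products of impulse responses on every input channel."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    scales = np.atleast_1d(np.asarray(impulse_scales, dtype=float))
    ref0 = system.reference()
    # unforced reference trajectory to subtract
    ref_traj = []
    s_ref = ref0
    for _ in range(horizon):
        s_ref = system.step(s_ref, None)
        ref_traj.append(system.state_vec(s_ref))
    ref_traj = np.asarray(ref_traj)

    n = len(system.state_vec(ref0))
    W = np.zeros((n, n))
    for i in range(system.n_inputs):
        e = np.zeros(system.n_inputs)
        for s in scales:
            responses = []
            for sign in (+1.0, -1.0):
                e_i = e.copy()
                e_i[i] = sign * s / dt
                st = system.step(ref0, e_i)
                traj = [system.state_vec(st)]
                for _ in range(horizon - 1):
                    st = system.step(st, None)
                    traj.append(system.state_vec(st))
                responses.append(np.asarray(traj) - ref_traj)
            delta = 0.5 * (responses[0] - responses[1])  # symmetrized, odd part
            W += dt * (delta.T @ delta) / (s * s * len(scales))
    return _finalize(W, threshold)


def empirical_observability_gramian(system, perturbation_scales=(0.5, 1.0),
                                    horizon: int = 50, dt: float = 1.0,
                                    threshold: float = 0.9) -> GramianResult:
    """Average inner products of output responses to initial-state
    perturbations along every state direction."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    scales = np.atleast_1d(np.asarray(perturbation_scales, dtype=float))
    ref0 = system.reference()
    ref_out = []
    s_ref = ref0
    for _ in range(horizon):
        ref_out.append(system.readout(s_ref))
        s_ref = system.step(s_ref, None)
    ref_out = np.asarray(ref_out)

    n = system.n_states
    W = np.zeros((n, n))
    for s in scales:
        D = np.zeros((n, ref_out.size))
        for j in range(n):
            outs = []
            for sign in (+1.0, -1.0):
                delta = np.zeros(n)
                delta[j] = sign * s
                st = system.perturb(ref0, delta)
                traj = []
                for _ in range(horizon):
                    traj.append(system.readout(st))
                    st = system.step(st, None)
                outs.append(np.asarray(traj) - ref_out)
            resp = 0.5 * (outs[0] - outs[1])
            resp[0] *= np.sqrt(0.5)  # trapezoid weight on the t=0 sample
            D[j] = resp.ravel()
        W += dt * (D @ D.T) / (s * s * len(scales))
    return _finalize(W, threshold)


def electrode_lower_bound(neural_system: RNNParams, model: SdeModel,
                          obs_matrix: np.ndarray, dt: float,
                          threshold: float = 0.9, horizon: int = 50,
                          scales=(0.1, 0.2)) -> tuple[int, int]:
    """Variance dimensions of the closed-loop association-layer Gramians:
    (stimulation bound, recording bound).

    These lower-bound the number of electrodes a prosthesis needs to steer
    and to observe the neural system. Probing impulse/perturbation scales
    default to 0.1–0.2 to stay in the near-linear regime of the rates.
    """
    sys = ClosedLoopAssociationSystem(neural_system, model, obs_matrix, dt)
    wc = empirical_controllability_gramian(sys, impulse_scales=scales,
                                           horizon=horizon, dt=1.0, threshold=threshold)
    wo = empirical_observability_gramian(sys, perturbation_scales=scales,
                                         horizon=horizon, dt=1.0, threshold=threshold)
    return wc.variance_dim, wo.variance_dim
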