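"""Simulated impairment and prosthetic restoration.

Impairment is modeled by adding Gaussian white noise to one synaptic weight
group of a trained neural system: the sensory input weights B, the
recurrent association weights A, or the motor readout C. A secondary RNN —
the prosthesis — records the firing rates of a subset of association
neurons (rows kept in C_EN) and injects stimulation current into a subset
(columns kept in B_EN) so that the association layer's pre-activation
becomes ``A x + B u + b + B_EN u_EN``. The neural system stays frozen;
only the prosthesis is trained, with the same backends used for the neural
system itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .environments import ParticleEnv, _GymEnvBase
from .linear_control import LqrCost
from .rnn_controller import RNNParams, RNNState, init_rnn, rnn_step
from .training import (
    Adam,
    DirectTrainConfig,
    LearningCurve,
    RLConfig,
    _clip_grad_norm,
    _collect_grads,
    _param_arrays,
    _require_linear_env,
    _rnn_graph_step,
    _tensors,
    train_rl,
)

__all__ = [
    "PerturbationSpec",
    "ElectrodeMask",
    "CompositeSystem",
    "CompositeController",
    "ProsthesisEnv",
    "perturb_weights",
    "make_electrode_mask",
    "composite_step",
    "train_prosthesis",
    "default_prosthesis",
]

_POPULATIONS = ("sensory", "association", "motor")


@dataclass(frozen=True)
class PerturbationSpec:
    """Which weight population to degrade, and how strongly.

    sigma is the standard deviation of the additive Gaussian noise applied
    elementwise to the chosen matrix group: sensory = first-layer input
    weights, association = all recurrent weights, motor = readout weights.
    """

    population: str
    sigma: float
    seed: int = 0

    def __post_init__(self):
        if self.population not in _POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}; expected one of {_POPULATIONS}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def perturb_weights(rnn: RNNParams, spec: PerturbationSpec) -> RNNParams:
    """Return a copy with N(0, sigma^2) noise added to one weight group;
    every other parameter is bit-identical to the input."""
    out = rnn.copy()
    if spec.sigma == 0:
        return out
    rng = np.random.default_rng(spec.seed)
    if spec.population == "sensory":
        out.layers[0].B_in += spec.sigma * rng.standard_normal(out.layers[0].B_in.shape)
    elif spec.population == "association":
        for layer in out.layers:
            layer.A_rec += spec.sigma * rng.standard_normal(layer.A_rec.shape)
    else:  # motor
        out.readout.C_out += spec.sigma * rng.standard_normal(out.readout.C_out.shape)
    return out


@dataclass(frozen=True)
class ElectrodeMask:
    """Index sets of association neurons the prosthesis can record from
    and stimulate. Indices address the concatenated association rates
    across layers. Empty sets give the no-prosthesis limit."""

    record_indices: np.ndarray
    stim_indices: np.ndarray
    n_assoc: int

    def __post_init__(self):
        for name in ("record_indices", "stim_indices"):
            idx = np.asarray(getattr(self, name), dtype=int)
            if len(np.unique(idx)) != len(idx):
                raise ValueError(f"{name} must be unique")
            if len(idx) and (idx.min() < 0 or idx.max() >= self.n_assoc):
                raise ValueError(f"{name} out of range [0, {self.n_assoc})")
            object.__setattr__(self, name, idx)

    @property
    def n_record(self) -> int:
        return len(self.record_indices)

    @property
    def n_stim(self) -> int:
        return len(self.stim_indices)

    @property
    def C_EN(self) -> np.ndarray:
        """Recording selection matrix (n_record x n_assoc)."""
        C = np.zeros((self.n_record, self.n_assoc))
        C[np.arange(self.n_record), self.record_indices] = 1.0
        return C

    @property
    def B_EN(self) -> np.ndarray:
        """Stimulation selection matrix (n_assoc x n_stim)."""
        B = np.zeros((self.n_assoc, self.n_stim))
        B[self.stim_indices, np.arange(self.n_stim)] = 1.0
        return B


def make_electrode_mask(n_assoc: int, fraction: float, seed: int = 0,
                        independent: bool = False) -> ElectrodeMask:
    """Sample round(fraction * n_assoc) electrode sites uniformly.

    By default the same sites serve recording and stimulation; with
    `independent=True` two disjoint draws are taken.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    k = int(round(fraction * n_assoc))
    rec = np.sort(rng.choice(n_assoc, size=k, replace=False))
    stim = np.sort(rng.choice(n_assoc, size=k, replace=False)) if independent else rec.copy()
    return ElectrodeMask(rec, stim, n_assoc)


def default_prosthesis(mask: ElectrodeMask, seed: int, width: int = 50,
                       output_gain: float = 5.0) -> RNNParams:
    """Prosthesis preset: one recurrent layer of `width` neurons reading
    the masked rates and emitting one stimulation current per electrode.

    The output gain bounds the stimulation amplitude; 5 comfortably covers
    the scale of perturbation-induced pre-activation currents. The readout
    weights start near zero so an untrained prosthesis is quiescent —
    stimulating at random would saturate the association neurons and both
    degrade behavior and kill the training gradient.
    """
    if mask.n_record == 0 or mask.n_stim == 0:
        raise ValueError("cannot build a prosthesis for an empty electrode mask")
    rnn = init_rnn([width], mask.n_record, mask.n_stim, seed, output_gain=output_gain)
    rnn.readout.C_out *= 0.01
    return rnn


# ---------------------------------------------------------------------------
# composite brain–prosthesis system


@dataclass
class CompositeSystem:
    """Environment + frozen neural system + trainable prosthesis, coupled
    through the electrode mask."""

    env: _GymEnvBase
    neural_system: RNNParams
    prosthesis: RNNParams | None
    mask: ElectrodeMask

    def __post_init__(self):
        if self.mask.n_assoc != self.neural_system.n_association:
            raise ValueError("mask size must match the association population")
        if self.prosthesis is not None and self.mask.n_record > 0:
            if self.prosthesis.input_dim != self.mask.n_record:
                raise ValueError("prosthesis input must match the recording channels")
            if self.prosthesis.output_dim != self.mask.n_stim:
                raise ValueError("prosthesis output must match the stimulation channels")

    def split_injection(self, u_EN: np.ndarray) -> list[np.ndarray | None]:
        """Distribute B_EN u_EN over the association layers."""
        full = self.mask.B_EN @ u_EN
        out: list[np.ndarray | None] = []
        start = 0
        for layer in self.neural_system.layers:
            seg = full[start:start + layer.size]
            out.append(seg if np.any(seg) else None)
            start += layer.size
        return out


def composite_step(
    sys: CompositeSystem,
    env_observation: np.ndarray,
    state: tuple[RNNState, RNNState | None],
) -> tuple[np.ndarray, tuple[RNNState, RNNState | None]]:
    """One synchronous tick of the coupled brain–prosthesis system.

    Order: (a) the prosthesis reads the one-tick-old masked association
    rates y_EN = C_EN x_N; (b) the prosthesis steps, producing stimulation
    u_EN; (c) the neural system steps on the environment observation with
    the extra current B_EN u_EN injected into its pre-activation; (d) the
    motor readout yields the environment control.
    """
    neural_state, prosthesis_state = state
    injections = None
    if sys.prosthesis is not None and sys.mask.n_record > 0 and sys.mask.n_stim > 0:
        y_EN = sys.mask.C_EN @ np.concatenate(neural_state.rates)
        prosthesis_state, u_EN = rnn_step(prosthesis_state, y_EN, sys.prosthesis)
        injections = sys.split_injection(u_EN)
    neural_state, control = rnn_step(neural_state, env_observation, sys.neural_system,
                                     injections=injections)
    return control, (neural_state, prosthesis_state)


class CompositeController:
    """Closed-loop adapter around :func:`composite_step` for rollouts."""

    def __init__(self, sys: CompositeSystem):
        self.sys = sys
        self.reset()

    def reset(self) -> None:
        self._state = (
            RNNState.zeros(self.sys.neural_system),
            RNNState.zeros(self.sys.prosthesis) if self.sys.prosthesis is not None else None,
        )

    def __call__(self, observation: np.ndarray) -> np.ndarray:
        control, self._state = composite_step(self.sys, observation, self._state)
        return control


class ProsthesisEnv(_GymEnvBase):
    """The composite system seen from the prosthesis: observations are the
    masked association rates, actions are stimulation currents, rewards
    come from the underlying task. Used by the RL backend."""

    def __init__(self, sys: CompositeSystem):
        if sys.mask.n_record == 0 or sys.mask.n_stim == 0:
            raise ValueError("RL prosthesis training needs a non-empty electrode mask")
        self.sys = sys
        self.observation_dim = sys.mask.n_record
        self.control_dim = sys.mask.n_stim
        self._neural_state: RNNState | None = None
        self._env_obs: np.ndarray | None = None

    def reset(self, seed: int | None = None) -> np.ndarray:
        self._env_obs = self.sys.env.reset(seed=seed)
        self._neural_state = RNNState.zeros(self.sys.neural_system)
        return self.sys.mask.C_EN @ np.concatenate(self._neural_state.rates)

    def step(self, u_EN) -> tuple[np.ndarray, float, bool, bool, dict]:
        assert self._neural_state is not None, "call reset() first"
        u_EN = np.atleast_1d(np.asarray(u_EN, dtype=float))
        injections = self.sys.split_injection(u_EN)
        self._neural_state, control = rnn_step(
            self._neural_state, self._env_obs, self.sys.neural_system, injections=injections)
        self._env_obs, reward, terminated, truncated, info = self.sys.env.step(control)
        y_EN = self.sys.mask.C_EN @ np.concatenate(self._neural_state.rates)
        return y_EN, reward, terminated, truncated, info


# ---------------------------------------------------------------------------
# prosthesis training


def train_prosthesis(sys: CompositeSystem, method: str, cfg,
                     cost: LqrCost | None = None) -> tuple[RNNParams, LearningCurve]:
    """Optimize the prosthesis only; the neural system stays frozen.

    `method` is "direct" (BPTT on the quadratic cost through the linear
    environment, `cfg` a DirectTrainConfig) or "rl" (policy gradient on the
    task reward, `cfg` an RLConfig).
    """
    if sys.prosthesis is None:
        raise ValueError("composite system has no prosthesis to train")
    if method == "direct":
        if cost is None:
            cost = LqrCost.identity(2, 1)
        return _train_prosthesis_direct(sys, cost, cfg)
    if method == "rl":
        prosthesis, curve = train_rl(ProsthesisEnv(sys), sys.prosthesis, cfg)
        return prosthesis, curve
    raise ValueError(f"unknown method {method!r}; expected 'direct' or 'rl'")


def _train_prosthesis_direct(sys: CompositeSystem, cost: LqrCost,
                             cfg: DirectTrainConfig) -> tuple[RNNParams, LearningCurve]:
    env = sys.env
    _require_linear_env(env)
    if env.config.obs_mode != "full_state":
        raise NotImplementedError("direct prosthesis training assumes full-state sensing")
    prosthesis = sys.prosthesis.copy()
    p_arrays = _param_arrays(prosthesis)
    opt = Adam(p_arrays, lr=cfg.learning_rate)
    curve = LearningCurve("mean_lqr_cost")
    rng = np.random.default_rng(cfg.seed)

    neural = sys.neural_system
    n_tensors_const = {k: Tensor(v) for k, v in _param_arrays(neural).items()}
    C_EN_T = Tensor(sys.mask.C_EN.T)
    # stimulation scattered back to per-layer segments
    B_EN = sys.mask.B_EN
    layer_slices = []
    start = 0
    for layer in neural.layers:
        layer_slices.append(slice(start, start + layer.size))
        start += layer.size

    dt = env.config.dt
    A_env = Tensor(env.model.A.T)
    B_env = Tensor(env.model.B.T)
    Qm, Rm = Tensor(cost.Q), Tensor(cost.R)
    grid = env._grid
    n_updates_per_epoch = max(1, cfg.trajectories_per_epoch // max(cfg.batch_size, 1))
    n_total = cfg.epochs * n_updates_per_epoch
    update_idx = 0

    for _epoch in range(cfg.epochs):
        for _update in range(n_updates_per_epoch):
            lr = cfg.learning_rate * (1.0 - update_idx / n_total) \
                if cfg.lr_schedule == "linear" else cfg.learning_rate
            update_idx += 1
            p_tensors = _tensors(p_arrays)
            batch = cfg.batch_size
            x = Tensor(grid[rng.integers(len(grid), size=batch)])
            n_hidden = [Tensor(np.zeros((batch, l.size))) for l in neural.layers]
            p_hidden = [Tensor(np.zeros((batch, l.size))) for l in prosthesis.layers]
            total = None
            for _t in range(cfg.episode_len):
                rates_cat = n_hidden[0] if len(n_hidden) == 1 else ag.concat(n_hidden, axis=1)
                y_EN = rates_cat @ C_EN_T
                p_hidden, u_EN, _ = _rnn_graph_step(p_tensors, prosthesis, p_hidden, y_EN)
                inj_full = u_EN @ Tensor(B_EN.T)
                injections = [
                    _slice_cols(inj_full, sl) if sl.stop > sl.start else None
                    for sl in layer_slices
                ]
                n_hidden, u, _ = _rnn_graph_step(n_tensors_const, neural, n_hidden, x,
                                                 injections=injections)
                step_cost = ((x @ Qm) * x).sum(axis=1) + ((u @ Rm) * u).sum(axis=1)
                total = step_cost if total is None else total + step_cost
                x = x + (x @ A_env + u @ B_env) * dt
            loss = (total * dt).mean()
            loss.backward()
            grads = _collect_grads(p_tensors)
            _clip_grad_norm(grads, cfg.max_grad_norm)
            opt.step(grads, lr=lr)
            curve.record(loss.data)
    return prosthesis, curve


def _slice_cols(t: Tensor, sl: slice) -> Tensor:
    """Differentiable column slice of a 2-D tensor."""
    n_cols = t.data.shape[1]

    def backward(g):
        full = np.zeros((g.shape[0], n_cols))
        full[:, sl] = g
        return (full,)

    return Tensor(t.data[:, sl], parents=(t,), backward=backward)
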