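"""Training backends for RNN controllers.

Three routes, matching the assumptions one can make about the environment:

* **direct** — backpropagation through time on the quadratic regulator cost
  with the (differentiable, known) environment inside the computation
  graph; only the controller parameters are updated.
* **oracle** — supervised distillation: an analytic LQG controller is
  rolled out to collect (observation, control) sequence pairs, and the RNN
  is regressed onto the oracle controls with MSE + BPTT.
* **rl** — a clipped-surrogate policy-gradient method (PPO-style) with
  generalized advantage estimation, a Gaussian action head on the bounded
  readout mean, and a linear value head on the top-layer rates. It supports
  the stateful recurrent policy by recomputing hidden states from episode
  start during updates.

All gradients come from the package's minimal reverse-mode autodiff; no
external deep-learning framework is required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _autograd as ag
from ._autograd import Tensor
from .dynamics import episode_rng
from .environments import ParticleEnv, _GymEnvBase
from .linear_control import LqgController, LqrCost
from .rnn_controller import RNNParams, RNNState

__all__ = [
    "DirectTrainConfig",
    "OracleTrainConfig",
    "RLConfig",
    "OracleDataset",
    "LearningCurve",
    "UnsupportedEnvironmentError",
    "Adam",
    "train_direct",
    "collect_oracle_dataset",
    "train_oracle",
    "train_rl",
]


class UnsupportedEnvironmentError(TypeError):
    """Raised when a training method's assumptions do not hold for the
    given environment (mirrors the method-selection table)."""


# ---------------------------------------------------------------------------
# configs and bookkeeping


@dataclass
class DirectTrainConfig:
    """End-to-end gradient training budget. Defaults follow the full
    protocol (10 epochs of 10k trajectories from a 100x100 start grid);
    scaled-down presets shrink `epochs`/`trajectories_per_epoch` only."""

    epochs: int = 10
    trajectories_per_epoch: int = 10_000
    grid_side: int = 100
    learning_rate: float = 1e-3
    lr_schedule: str = "linear"  # "linear" decay to zero, or "constant"
    episode_len: int = 100
    batch_size: int = 50
    max_grad_norm: float = 1.0  # 0 disables clipping
    freeze: tuple[str, ...] = ()  # parameter names excluded from updates, e.g. ("L0.A",)
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.trajectories_per_epoch, self.batch_size) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class OracleTrainConfig:
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    seed: int = 0


@dataclass
class RLConfig:
    """Policy-gradient budget. `episodes` counts environment episodes;
    the learning rate decays linearly to zero over the run."""

    episodes: int = 20_000
    learning_rate: float = 2e-4
    gamma: float = 0.99
    gae_lambda: float = 0.95
    clip_range: float = 0.2
    entropy_coef: float = 0.0
    value_coef: float = 0.5
    epochs_per_update: int = 10
    episodes_per_update: int = 16
    init_log_std: float = -0.5
    max_grad_norm: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")


@dataclass
class OracleDataset:
    """Paired observation and oracle-control sequences, shapes
    (episodes, steps, obs_dim) and (episodes, steps, control_dim)."""

    inputs: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        if len(self.inputs) != len(self.labels):
            raise ValueError("inputs and labels must pair up")

    def __len__(self) -> int:
        return len(self.inputs)


@dataclass
class LearningCurve:
    """Per-update training metric plus optional evaluation snapshots."""

    metric_name: str
    values: list[float] = field(default_factory=list)
    eval_updates: list[int] = field(default_factory=list)
    eval_values: list[float] = field(default_factory=list)

    def record(self, value: float) -> None:
        self.values.append(float(value))

    def snapshot(self, value: float) -> None:
        self.eval_updates.append(len(self.values))
        self.eval_values.append(float(value))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"update": np.arange(len(self.values)),
                      self.metric_name: self.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adaptive-moment gradient descent on a dict of named arrays,
    updated in place."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        for k, g in grads.items():
            if g is None:
                continue
            p = self.params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p -= lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# parameter <-> tensor bridging


def _param_arrays(rnn: RNNParams) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for i, l in enumerate(rnn.layers):
        out[f"L{i}.A"] = l.A_rec
        out[f"L{i}.B"] = l.B_in
        out[f"L{i}.b"] = l.bias
    out["out.C"] = rnn.readout.C_out
    out["out.b"] = rnn.readout.bias
    return out


def _tensors(arrays: dict[str, np.ndarray]) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=True) for k, v in arrays.items()}


def _collect_grads(tensors: dict[str, Tensor]) -> dict[str, np.ndarray]:
    return {k: (t.grad if t.grad is not None else np.zeros_like(t.data))
            for k, t in tensors.items()}


def _rnn_graph_step(tensors: dict[str, Tensor], rnn: RNNParams,
                    hidden: list[Tensor], inp: Tensor,
                    injections: list[Tensor | None] | None = None,
                    ) -> tuple[list[Tensor], Tensor, Tensor]:
    """Batched differentiable network tick.

    `hidden[i]` has shape (batch, n_i); `inp` (batch, obs_dim). Returns the
    new hidden rates, the bounded output mean, and the top-layer rates.
    `injections` optionally adds a pre-activation current per layer
    (prosthetic stimulation).
    """
    u = inp
    new_hidden: list[Tensor] = []
    for i in range(len(rnn.layers)):
        pre = hidden[i] @ tensors[f"L{i}.A"].T_() + u @ tensors[f"L{i}.B"].T_() + tensors[f"L{i}.b"]
        if injections is not None and injections[i] is not None:
            pre = pre + injections[i]
        u = pre.tanh()
        new_hidden.append(u)
    out = (u @ tensors["out.C"].T_() + tensors["out.b"]).tanh() * rnn.readout.output_gain
    return new_hidden, out, u


# ---------------------------------------------------------------------------
# direct optimization with the environment in the loop


def _require_linear_env(env) -> None:
    model = getattr(env, "model", None)
    if model is None or not getattr(model, "is_linear", False):
        raise UnsupportedEnvironmentError(
            "direct optimization needs a differentiable (here: linear, known) "
            "environment; use the oracle or RL backend instead"
        )


def train_direct(env: ParticleEnv, rnn: RNNParams, cost: LqrCost,
                 cfg: DirectTrainConfig) -> tuple[RNNParams, LearningCurve]:
    """Gradient descent on the quadratic cost through on-the-fly rollouts.

    The environment dynamics sit inside the unrolled graph but their
    parameters are constants; only the controller is updated. Returns a
    copy of the parameters after `cfg.epochs` epochs (0 epochs returns the
    input unchanged) together with the per-update loss curve.
    """
    _require_linear_env(env)
    rnn = rnn.copy()
    arrays = _param_arrays(rnn)
    opt = Adam(arrays, lr=cfg.learning_rate)
    curve = LearningCurve("mean_lqr_cost")
    rng = np.random.default_rng(cfg.seed)

    dt = env.config.dt
    A_env = Tensor(env.model.A.T)  # pre-transposed for row-vector states
    B_env = Tensor(env.model.B.T)
    Qm, Rm = cost.Q, cost.R
    C_obs = env.obs_model.obs_matrix
    obs_noise_sd = float(np.sqrt(env.obs_model.noise.obs_cov[0, 0])) \
        if np.any(env.obs_model.noise.obs_cov) else 0.0
    proc_sd = float(np.sqrt(env.config.process_var))
    full_state_obs = env.config.obs_mode == "full_state"
    grid = env._grid

    n_updates_per_epoch = max(1, cfg.trajectories_per_epoch // max(cfg.batch_size, 1))
    n_total = cfg.epochs * n_updates_per_epoch
    update_idx = 0
    for _epoch in range(cfg.epochs):
        for _update in range(n_updates_per_epoch):
            lr = cfg.learning_rate * (1.0 - update_idx / n_total) \
                if cfg.lr_schedule == "linear" else cfg.learning_rate
            update_idx += 1
            tensors = _tensors(arrays)
            batch = cfg.batch_size
            x = Tensor(grid[rng.integers(len(grid), size=batch)])
            hidden = [Tensor(np.zeros((batch, l.size))) for l in rnn.layers]
            total = None
            for _t in range(cfg.episode_len):
                if full_state_obs:
                    y = x
                else:
                    # reparameterized sensor noise keeps the pathwise
                    # gradient exact through the observation channel
                    y = x @ Tensor(C_obs.T)
                    if obs_noise_sd > 0:
                        y = y + Tensor(obs_noise_sd
                                       * rng.standard_normal((batch, C_obs.shape[0])))
                hidden, u, _ = _rnn_graph_step(tensors, rnn, hidden, y)
                step_cost = ((x @ Tensor(Qm)) * x).sum(axis=1) + ((u @ Tensor(Rm)) * u).sum(axis=1)
                total = step_cost if total is None else total + step_cost
                x_next = x + (x @ A_env + u @ B_env) * dt
                if proc_sd > 0:
                    x_next = x_next + Tensor(
                        np.sqrt(dt) * proc_sd * rng.standard_normal((batch, x.shape[1])))
                x = x_next
            loss = (total * dt).mean()
            loss.backward()
            grads = _collect_grads(tensors)
            for name in cfg.freeze:
                grads[name] = np.zeros_like(grads[name])
            _clip_grad_norm(grads, cfg.max_grad_norm)
            opt.step(grads, lr=lr)
            curve.record(loss.data)
    return rnn, curve


# ---------------------------------------------------------------------------
# oracle distillation


def collect_oracle_dataset(lqg: LqgController, env: ParticleEnv, n_episodes: int,
                           seed: int, episode_len: int | None = None) -> OracleDataset:
    """Roll the analytic controller through the environment and record
    (observation, control) pairs for supervised distillation."""
    model = getattr(env, "model", None)
    if model is None or not getattr(model, "is_linear", False):
        raise UnsupportedEnvironmentError("the oracle backend needs a known linear environment")
    T = episode_len or env.config.max_steps
    grid = env._grid
    obs_model = env.obs_model
    Y = np.zeros((n_episodes, T, obs_model.obs_dim))
    U = np.zeros((n_episodes, T, model.control_dim))
    from .dynamics import rollout  # local import to avoid cycle at module load

    for ep in range(n_episodes):
        rng = episode_rng(seed, ep)
        x0 = grid[rng.integers(len(grid))]
        traj = rollout(model, lqg, obs_model, x0, T, env.config.dt, rng)
        Y[ep] = traj.observations
        U[ep] = traj.controls
    return OracleDataset(inputs=Y, labels=U)


def train_oracle(rnn: RNNParams, data: OracleDataset,
                 cfg: OracleTrainConfig) -> tuple[RNNParams, LearningCurve]:
    """Sequence regression of the RNN onto oracle controls (MSE + BPTT)."""
    if len(data) == 0:
        raise ValueError("oracle dataset is empty")
    rnn = rnn.copy()
    arrays = _param_arrays(rnn)
    opt = Adam(arrays, lr=cfg.learning_rate)
    curve = LearningCurve("train_mse")
    rng = np.random.default_rng(cfg.seed)

    n_val = max(1, int(len(data) * cfg.val_fraction)) if len(data) > 1 else 0
    perm = rng.permutation(len(data))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if len(train_idx) == 0:
        train_idx = perm

    def batch_mse(idx: np.ndarray, tensors: dict[str, Tensor]) -> Tensor:
        Y = data.inputs[idx]   # (b, T, k)
        U = data.labels[idx]
        b, T, _ = Y.shape
        hidden = [Tensor(np.zeros((b, l.size))) for l in rnn.layers]
        err = None
        for t in range(T):
            hidden, u_hat, _ = _rnn_graph_step(tensors, rnn, hidden, Tensor(Y[:, t]))
            sq = ((u_hat - Tensor(U[:, t])) ** 2.0).sum(axis=1)
            err = sq if err is None else err + sq
        return (err * (1.0 / T)).mean()

    def eval_mse(idx: np.ndarray) -> float:
        if len(idx) == 0:
            return float("nan")
        tensors = _tensors(arrays)
        return float(batch_mse(idx, tensors).data)

    for _epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            tensors = _tensors(arrays)
            loss = batch_mse(idx, tensors)
            loss.backward()
            opt.step(_collect_grads(tensors))
            curve.record(loss.data)
        curve.snapshot(eval_mse(val_idx))
    return rnn, curve


# ---------------------------------------------------------------------------
# reinforcement learning (clipped-surrogate policy gradient)


@dataclass
class _Episode:
    obs: np.ndarray      # (T, k)
    actions: np.ndarray  # (T, m)
    rewards: np.ndarray  # (T,)
    logps: np.ndarray    # (T,)
    values: np.ndarray   # (T,)
    terminated: bool


def _policy_rollout(env: _GymEnvBase, rnn: RNNParams, extra: dict[str, np.ndarray],
                    seed: int, rng: np.random.Generator,
                    deterministic: bool = False, max_steps: int = 10_000) -> _Episode:
    """Run one episode with Gaussian exploration around the readout mean."""
    from .rnn_controller import rnn_step

    log_std = extra["log_std"]
    std = np.exp(log_std)
    w_v, b_v = extra["w_v"], extra["b_v"]
    obs = env.reset(seed=seed)
    state = RNNState.zeros(rnn)
    rows: list[tuple] = []
    for _t in range(max_steps):
        state, mu = rnn_step(state, obs, rnn)
        value = float(state.rates[-1] @ w_v + b_v[0])
        if deterministic:
            a = mu
            logp = 0.0
        else:
            a = mu + std * rng.standard_normal(mu.shape)
            z = (a - mu) / std
            # constant terms dropped: only log-prob differences enter the ratio
            logp = float(-0.5 * (z @ z) - log_std.sum())
        nxt, r, terminated, truncated, _ = env.step(a)
        rows.append((obs, a, r, logp, value))
        obs = nxt
        if terminated or truncated:
            break
    o, a, r, lp, v = map(np.asarray, zip(*rows))
    return _Episode(o, a, r, lp, v, terminated)


def _gae(ep: _Episode, gamma: float, lam: float) -> tuple[np.ndarray, np.ndarray]:
    T = len(ep.rewards)
    adv = np.zeros(T)
    last = 0.0
    # terminal value is zero: episodes end by success/failure/timeout
    for t in reversed(range(T)):
        v_next = ep.values[t + 1] if t + 1 < T else 0.0
        delta = ep.rewards[t] + gamma * v_next - ep.values[t]
        last = delta + gamma * lam * last
        adv[t] = last
    return adv, adv + ep.values


def train_rl(env: _GymEnvBase, rnn: RNNParams, cfg: RLConfig,
             extra_params: dict[str, np.ndarray] | None = None,
             ) -> tuple[RNNParams, LearningCurve]:
    """PPO-style training of the recurrent policy.

    Episodes are collected in batches, advantages come from generalized
    advantage estimation, and each update runs several epochs of the
    clipped surrogate plus value loss over the batch, recomputing hidden
    states from each episode's start so the recurrent policy stays exact.
    """
    if not (hasattr(env, "reset") and hasattr(env, "step")):
        raise UnsupportedEnvironmentError("RL needs the gym-style reset/step contract")
    rnn = rnn.copy()
    arrays = _param_arrays(rnn)
    if extra_params is None:
        extra_params = {}
    extra_params.setdefault("log_std", np.full(rnn.output_dim, cfg.init_log_std))
    extra_params.setdefault("w_v", np.zeros(rnn.layers[-1].size))
    extra_params.setdefault("b_v", np.zeros(1))
    all_arrays = {**arrays, **{f"x.{k}": v for k, v in extra_params.items()}}
    opt = Adam(all_arrays, lr=cfg.learning_rate)
    curve = LearningCurve("mean_episode_reward")
    rng = np.random.default_rng(cfg.seed)

    n_updates = max(1, cfg.episodes // cfg.episodes_per_update)
    ep_counter = 0
    for update in range(n_updates):
        lr = cfg.learning_rate * (1.0 - update / n_updates)
        episodes = []
        for _ in range(cfg.episodes_per_update):
            ep_seed = int(rng.integers(2 ** 31))
            episodes.append(_policy_rollout(env, rnn, extra_params, ep_seed, rng))
            ep_counter += 1
        curve.record(np.mean([ep.rewards.sum() for ep in episodes]))

        advs, rets = zip(*(_gae(ep, cfg.gamma, cfg.gae_lambda) for ep in episodes))
        flat_adv = np.concatenate(advs)
        adv_mean, adv_std = flat_adv.mean(), flat_adv.std() + 1e-8

        # pad episodes to a rectangular batch with a validity mask
        T = max(len(ep.rewards) for ep in episodes)
        b = len(episodes)
        k, m = episodes[0].obs.shape[1], episodes[0].actions.shape[1]
        O = np.zeros((b, T, k)); A = np.zeros((b, T, m))
        ADV = np.zeros((b, T)); RET = np.zeros((b, T)); LP = np.zeros((b, T))
        M = np.zeros((b, T))
        for i, ep in enumerate(episodes):
            n = len(ep.rewards)
            O[i, :n] = ep.obs; A[i, :n] = ep.actions
            ADV[i, :n] = (advs[i] - adv_mean) / adv_std
            RET[i, :n] = rets[i]; LP[i, :n] = ep.logps; M[i, :n] = 1.0
        mask = Tensor(M)
        n_valid = M.sum()

        for _epoch in range(cfg.epochs_per_update):
            tensors = _tensors(arrays)
            xt = {k2: Tensor(v, requires_grad=True) for k2, v in extra_params.items()}
            hidden = [Tensor(np.zeros((b, l.size))) for l in rnn.layers]
            pg_loss = None
            v_loss = None
            for t in range(T):
                hidden, mu, top = _rnn_graph_step(tensors, rnn, hidden, Tensor(O[:, t]))
                std = xt["log_std"].exp()
                z = (Tensor(A[:, t]) - mu) / std
                logp = (z ** 2.0 * -0.5 - xt["log_std"]).sum(axis=1)
                ratio = (logp - Tensor(LP[:, t])).exp()
                adv_t = Tensor(ADV[:, t])
                surr = ag.minimum(ratio * adv_t,
                                  ag.clip(ratio, 1 - cfg.clip_range, 1 + cfg.clip_range) * adv_t)
                v_pred = (top @ _colvec(xt["w_v"])).sum(axis=1) + xt["b_v"].sum()
                v_err = (v_pred - Tensor(RET[:, t])) ** 2.0
                mt = Tensor(M[:, t])
                pg_term = (surr * mt).sum()
                v_term = (v_err * mt).sum()
                pg_loss = pg_term if pg_loss is None else pg_loss + pg_term
                v_loss = v_term if v_loss is None else v_loss + v_term
            entropy = xt["log_std"].sum()
            loss = (pg_loss * -1.0 + v_loss * cfg.value_coef) * (1.0 / n_valid) \
                - entropy * cfg.entropy_coef
            loss.backward()
            grads = _collect_grads(tensors)
            grads.update({f"x.{k2}": (t.grad if t.grad is not None else np.zeros_like(t.data))
                          for k2, t in xt.items()})
            _clip_grad_norm(grads, cfg.max_grad_norm)
            opt.step(grads, lr=lr)
    return rnn, curve


def _colvec(t: Tensor) -> Tensor:
    """View a 1-D tensor as a column matrix inside the graph."""
    n = t.data.shape[0]
    out = Tensor(t.data.reshape(n, 1), parents=(t,),
                 backward=lambda g: (g.reshape(n),))
    return out


def _clip_grad_norm(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values() if g is not None))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            if g is not None:
                g *= scale
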