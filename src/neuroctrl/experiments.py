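"""Reproducible experiment driver.

Named presets cover every figure-level experiment: training each backend on
the particle task, RL on the pendulum, perturbation/restoration sweeps, and
the electrode-coverage sweep with Gramian bounds. Budgets come in two
flavors — ``full`` runs the full-scale protocol, ``desk`` is a
scaled-down surrogate that finishes on a laptop CPU while preserving the
qualitative claims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .dynamics import episode_rng, rollout
from .environments import Outcome, ParticleEnv, ParticleTaskConfig, PendulumEnv, PendulumTaskConfig
from .gramian_analysis import electrode_lower_bound
from .linear_control import LinearSystem, LqgController, LqrCost, lqr_cost_of_trajectory
from .perturbation_prosthesis import (
    CompositeController,
    CompositeSystem,
    PerturbationSpec,
    default_prosthesis,
    make_electrode_mask,
    perturb_weights,
    train_prosthesis,
)
from .rnn_controller import RNNController, RNNParams, particle_rnn, pendulum_rnn
from .training import (
    DirectTrainConfig,
    OracleTrainConfig,
    RLConfig,
    collect_oracle_dataset,
    train_direct,
    train_oracle,
    train_rl,
)

__all__ = [
    "ExperimentConfig",
    "PRESETS",
    "run_experiment",
    "evaluate",
    "particle_costs",
    "make_lqg_oracle",
    "train_particle_direct",
    "restoration_sweep",
    "coverage_sweep",
]

EVAL_SEED_OFFSET = 10_000  # evaluation episodes never share training seeds


class ExperimentConfig(BaseModel):
    """Validated experiment description (the YAML schema)."""

    name: str
    environment: str = Field(pattern="^(particle|pendulum)$")
    method: str = Field(pattern="^(direct|oracle|rl)$")
    budget: str = Field(default="desk", pattern="^(full|desk)$")
    seed: int = 0
    obs_mode: str | None = None
    perturb_populations: list[str] = []
    perturb_sigmas: list[float] = [0.1, 0.25, 0.5, 1.0]
    mask_fractions: list[float] = []
    out_dir: str = "results"

    @field_validator("perturb_sigmas", "mask_fractions")
    @classmethod
    def _non_negative(cls, v):
        if any(x < 0 for x in v):
            raise ValueError("sweep values must be non-negative")
        return v


PRESETS: dict[str, dict] = {
    "particle-direct": dict(name="particle-direct", environment="particle", method="direct"),
    "particle-oracle": dict(name="particle-oracle", environment="particle", method="oracle",
                            obs_mode="noisy_position"),
    "particle-rl": dict(name="particle-rl", environment="particle", method="rl",
                        obs_mode="noisy_position"),
    "pendulum-rl": dict(name="pendulum-rl", environment="pendulum", method="rl"),
    "restoration-direct": dict(name="restoration-direct", environment="particle",
                               method="direct",
                               perturb_populations=["sensory", "association", "motor"]),
    "coverage-sweep": dict(name="coverage-sweep", environment="particle", method="direct",
                           perturb_populations=["sensory"],
                           mask_fractions=[0.02, 0.05, 0.1, 0.5, 1.0]),
}


def get_preset(name: str, **overrides) -> ExperimentConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return ExperimentConfig(**{**PRESETS[name], **overrides})


# ---------------------------------------------------------------------------
# evaluation


def evaluate(controller, env, n_episodes: int, seed: int) -> dict:
    """Closed-loop evaluation over seeded episodes disjoint from training.

    Returns mean/median/95% CI of the episode return, the success rate, and
    mean episode length. n_episodes = 0 yields an empty, flagged summary.
    """
    if n_episodes == 0:
        return {"n": 0, "empty": True}
    returns, successes, lengths = [], [], []
    for ep in range(n_episodes):
        obs = env.reset(seed=EVAL_SEED_OFFSET + seed + ep)
        if hasattr(controller, "reset"):
            controller.reset()
        total, steps = 0.0, 0
        terminated = truncated = False
        info: dict = {}
        while not (terminated or truncated):
            obs, r, terminated, truncated, info = env.step(controller(obs))
            total += r
            steps += 1
        status = info.get("status")
        outcome = status.outcome if status is not None else None
        returns.append(total)
        lengths.append(steps)
        successes.append(outcome in (Outcome.SUCCESS, Outcome.TIMEOUT))
    returns = np.asarray(returns)
    half = 1.96 * returns.std(ddof=1) / np.sqrt(len(returns)) if len(returns) > 1 else 0.0
    return {
        "n": n_episodes,
        "mean_return": float(returns.mean()),
        "median_return": float(np.median(returns)),
        "ci_low": float(returns.mean() - half),
        "ci_high": float(returns.mean() + half),
        "success_rate": float(np.mean(successes)),
        "mean_length": float(np.mean(lengths)),
    }


def particle_costs(controller, starts: np.ndarray, dt: float = 0.1,
                   n_steps: int = 100, cost: LqrCost | None = None,
                   obs_model=None, seed: int = 0) -> np.ndarray:
    """Quadratic regulator cost of fixed-length particle episodes from the
    given start states (deterministic plant; observation noise only if the
    observation model carries any)."""
    from .dynamics import NoiseSpec, ObservationModel
    from .environments import double_integrator_model

    cost = cost or LqrCost.identity(2, 1)
    model = double_integrator_model(NoiseSpec.zero(2, 1))
    obs_model = obs_model or ObservationModel.full_state(2)
    out = np.zeros(len(starts))
    for i, x0 in enumerate(starts):
        rng = episode_rng(seed, i)
        traj = rollout(model, controller, obs_model, x0, n_steps, dt, rng)
        out[i] = lqr_cost_of_trajectory(traj, cost)
    return out


def eval_start_grid(n: int = 100, extent: float = 1.0, seed: int = 123) -> np.ndarray:
    """Held-out start states: uniform draws over the start square."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-extent, extent, size=(n, 2))


# ---------------------------------------------------------------------------
# building blocks reused by scripts and acceptance tests


def make_lqg_oracle(config: ParticleTaskConfig | None = None,
                    design_process_var: float = 0.01) -> LqgController:
    """Analytic LQG baseline for the particle task. The Kalman filter is
    synthesized with a nonzero design process covariance so its steady
    gain keeps correcting even on the deterministic plant."""
    from .dynamics import NoiseSpec
    from .environments import double_integrator_model

    config = config or ParticleTaskConfig()
    model = double_integrator_model(NoiseSpec.zero(2, 1))
    obs = config.observation_model()
    system = LinearSystem(model.A, model.B, obs.obs_matrix,
                          noise_spec_for(obs, config))
    return LqgController(system, LqrCost.identity(2, 1), config.dt,
                         design_process_cov=design_process_var * np.eye(2))


def noise_spec_for(obs, config):
    from .dynamics import NoiseSpec
    obs_cov = obs.noise.obs_cov
    if not np.any(obs_cov):
        # PD observation covariance required for filter synthesis
        obs_cov = 1e-9 * np.eye(obs.obs_dim)
    return NoiseSpec(config.process_var * np.eye(2), obs_cov)


def train_particle_direct(seed: int, epochs: int = 2, trajectories_per_epoch: int = 1000,
                          obs_mode: str = "full_state") -> RNNParams:
    """Direct-backend particle training at the scaled-down budget."""
    config = ParticleTaskConfig(obs_mode=obs_mode)
    env = ParticleEnv(config)
    rnn = particle_rnn(seed, obs_dim=env.observation_dim)
    cfg = DirectTrainConfig(epochs=epochs, trajectories_per_epoch=trajectories_per_epoch,
                            batch_size=10, seed=seed)
    trained, _ = train_direct(env, rnn, LqrCost.identity(2, 1), cfg)
    return trained


# ---------------------------------------------------------------------------
# sweeps (the machine-readable analogues of the restoration figures)


def restoration_sweep(neural: RNNParams, populations: list[str], sigmas: list[float],
                      seed: int, method: str = "direct",
                      train_cfg: DirectTrainConfig | RLConfig | None = None,
                      mask_fraction: float = 1.0, n_eval: int = 50) -> pd.DataFrame:
    """Perturb each population at each strength, train a prosthesis, and
    tabulate evaluation losses against the perturbed and unperturbed
    baselines."""
    env = ParticleEnv(ParticleTaskConfig())
    starts = eval_start_grid(n_eval, seed=seed + 777)
    base_costs = particle_costs(RNNController(neural), starts)
    rows = []
    for population in populations:
        for sigma in sigmas:
            spec = PerturbationSpec(population, sigma, seed=seed)
            perturbed = perturb_weights(neural, spec)
            pert_costs = particle_costs(RNNController(perturbed), starts)
            mask = make_electrode_mask(neural.n_association, mask_fraction, seed=seed)
            prosthesis = default_prosthesis(mask, seed=seed + 1)
            comp = CompositeSystem(env, perturbed, prosthesis, mask)
            cfg = train_cfg or DirectTrainConfig(epochs=6, trajectories_per_epoch=600,
                                                 batch_size=10, learning_rate=7e-3, seed=seed)
            trained, _ = train_prosthesis(comp, method, cfg)
            comp_trained = CompositeSystem(env, perturbed, trained, mask)
            rest_costs = particle_costs(CompositeController(comp_trained), starts)
            rows.append({
                "population": population, "sigma": sigma,
                "mask_fraction": mask_fraction, "seed": seed,
                "unperturbed_cost": base_costs.mean(),
                "perturbed_cost": pert_costs.mean(),
                "restored_cost": rest_costs.mean(),
            })
    return pd.DataFrame(rows)


def coverage_sweep(neural: RNNParams, fractions: list[float], sigma: float,
                   seed: int, population: str = "sensory",
                   train_cfg: DirectTrainConfig | None = None,
                   n_eval: int = 50) -> pd.DataFrame:
    """Restoration quality as a function of electrode coverage."""
    env = ParticleEnv(ParticleTaskConfig())
    starts = eval_start_grid(n_eval, seed=seed + 777)
    base_costs = particle_costs(RNNController(neural), starts)
    perturbed = perturb_weights(neural, PerturbationSpec(population, sigma, seed=seed))
    pert_costs = particle_costs(RNNController(perturbed), starts)
    rows = []
    for fraction in fractions:
        mask = make_electrode_mask(neural.n_association, fraction, seed=seed)
        if mask.n_record == 0:
            restored = pert_costs.mean()
        else:
            prosthesis = default_prosthesis(mask, seed=seed + 1)
            comp = CompositeSystem(env, perturbed, prosthesis, mask)
            cfg = train_cfg or DirectTrainConfig(epochs=6, trajectories_per_epoch=600,
                                                 batch_size=10, learning_rate=7e-3, seed=seed)
            trained, _ = train_prosthesis(comp, "direct", cfg)
            restored = particle_costs(
                CompositeController(CompositeSystem(env, perturbed, trained, mask)), starts
            ).mean()
        rows.append({
            "fraction": fraction, "n_electrodes": mask.n_record, "sigma": sigma,
            "seed": seed, "unperturbed_cost": base_costs.mean(),
            "perturbed_cost": pert_costs.mean(), "restored_cost": restored,
        })
    return pd.DataFrame(rows)


def save_phase_plot(trajectories, path: str | Path, labels=None) -> None:
    """Phase-space portrait (position vs velocity) of a few episodes."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    for i, traj in enumerate(trajectories):
        label = labels[i] if labels else None
        ax.plot(traj.states[:, 0], traj.states[:, 1], lw=1, label=label)
    ax.plot(0, 0, "k+", ms=10)
    ax.set_xlabel("position")
    ax.set_ylabel("velocity")
    if labels:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# orchestration


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Execute one named experiment end to end and write its artifacts
    (learning curve CSV, evaluation JSON, sweep CSVs, Gramian JSON) under
    `cfg.out_dir`. Returns a summary dict. Idempotent given the seed."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    desk = cfg.budget == "desk"
    summary: dict = {"name": cfg.name, "budget": cfg.budget, "seed": cfg.seed}

    if cfg.environment == "particle":
        obs_mode = cfg.obs_mode or ("full_state" if cfg.method == "direct" else "noisy_position")
        config = ParticleTaskConfig(obs_mode=obs_mode)
        env = ParticleEnv(config)
        rnn = particle_rnn(cfg.seed, obs_dim=env.observation_dim)
        cost = LqrCost.identity(2, 1)
        if cfg.method == "direct":
            tcfg = DirectTrainConfig(epochs=2 if desk else 10,
                                     trajectories_per_epoch=1000 if desk else 10_000,
                                     batch_size=10, seed=cfg.seed)
            trained, curve = train_direct(env, rnn, cost, tcfg)
        elif cfg.method == "oracle":
            oracle = make_lqg_oracle(config)
            data = collect_oracle_dataset(oracle, env, 2000 if desk else 10_000, cfg.seed)
            ocfg = OracleTrainConfig(epochs=6 if desk else 10, seed=cfg.seed)
            trained, curve = train_oracle(rnn, data, ocfg)
        else:
            rcfg = RLConfig(episodes=2000 if desk else 500_000, seed=cfg.seed)
            trained, curve = train_rl(env, rnn, rcfg)
        curve.to_csv(out / f"{cfg.name}_curve.csv")
        eval_env = ParticleEnv(config)
        summary["evaluation"] = evaluate(RNNController(trained), eval_env, 100, cfg.seed)
        starts = eval_start_grid(100, seed=cfg.seed + 777)
        summary["mean_lqr_cost"] = float(particle_costs(RNNController(trained), starts).mean())

        # sample trajectories + phase portrait (untrained vs trained vs optimal)
        from .dynamics import NoiseSpec
        from .environments import double_integrator_model
        model = double_integrator_model(NoiseSpec.zero(2, 1))
        obs_full = config.observation_model() if obs_mode == "full_state" \
            else ParticleTaskConfig(obs_mode="full_state").observation_model()
        x0 = np.array([1.0, 1.0])
        samples, labels = [], []
        for label, ctrl in [("untrained", RNNController(particle_rnn(cfg.seed, env.observation_dim))),
                            ("trained", RNNController(trained)),
                            ("optimal", make_lqg_oracle(ParticleTaskConfig(obs_mode="full_state")))]:
            obs_m = env.obs_model if label != "optimal" else obs_full
            traj = rollout(model, ctrl, obs_m, x0, 100, config.dt, episode_rng(cfg.seed, 0))
            traj.to_csv(out / f"{cfg.name}_traj_{label}.csv")
            samples.append(traj)
            labels.append(label)
        save_phase_plot(samples, out / f"{cfg.name}_phase.png", labels)

        if cfg.perturb_populations and not cfg.mask_fractions:
            df = restoration_sweep(trained, cfg.perturb_populations, cfg.perturb_sigmas,
                                   cfg.seed, method="direct" if cfg.method != "rl" else "rl")
            df.to_csv(out / f"{cfg.name}_restoration.csv", index=False)
            summary["restoration_rows"] = len(df)
        if cfg.mask_fractions:
            df = coverage_sweep(trained, cfg.mask_fractions, sigma=0.5, seed=cfg.seed)
            df.to_csv(out / f"{cfg.name}_coverage.csv", index=False)
            bound_c, bound_o = electrode_lower_bound(
                trained, env.model, env.obs_model.obs_matrix, config.dt)
            (out / f"{cfg.name}_gramian.json").write_text(json.dumps(
                {"stimulation_bound": bound_c, "recording_bound": bound_o}, indent=2))
            summary["gramian_bounds"] = [bound_c, bound_o]
    else:  # pendulum
        config = PendulumTaskConfig()
        env = PendulumEnv(config)
        rnn = pendulum_rnn(cfg.seed, obs_dim=env.observation_dim)
        if cfg.method != "rl":
            raise ValueError("the pendulum task is nonlinear and unknown to the "
                             "controller: only the RL backend applies")
        rcfg = RLConfig(episodes=500 if desk else 800_000, episodes_per_update=8, seed=cfg.seed)
        trained, curve = train_rl(env, rnn, rcfg)
        curve.to_csv(out / f"{cfg.name}_curve.csv")
        summary["evaluation"] = evaluate(RNNController(trained), PendulumEnv(config), 20, cfg.seed)

    (out / f"{cfg.name}_summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
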