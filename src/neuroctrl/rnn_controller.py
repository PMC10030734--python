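"""Continuous-time recurrent network model of the neural system.

Each layer follows leaky membrane dynamics ``tau * dv/dt = -v + A h(v) +
B u + b`` with tanh rates. Split-step Euler integration at a step size
equal to the time constant collapses this to the familiar discrete update
``x_t = tanh(A x_{t-1} + B u_t + b)``; a tanh readout ``y = gain *
tanh(C x + c)`` produces the motor command. We interpret the input weights
B as the sensory population, the recurrent weights A as the association
population, and the readout C as the motor population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RNNLayerParams",
    "ReadoutParams",
    "RNNParams",
    "RNNState",
    "RNNController",
    "rnn_step",
    "continuous_rnn_derivative",
    "init_rnn",
    "particle_rnn",
    "pendulum_rnn",
]


@dataclass
class RNNLayerParams:
    """One recurrent layer: recurrent weights, input weights, bias, and the
    membrane time constant tau (seconds)."""

    A_rec: np.ndarray
    B_in: np.ndarray
    bias: np.ndarray
    tau: float = 1.0

    def __post_init__(self):
        self.A_rec = np.asarray(self.A_rec, dtype=np.float64)
        self.B_in = np.atleast_2d(np.asarray(self.B_in, dtype=np.float64))
        self.bias = np.asarray(self.bias, dtype=np.float64)
        n = self.A_rec.shape[0]
        if self.A_rec.shape != (n, n):
            raise ValueError("A_rec must be square")
        if self.B_in.shape[0] != n or self.bias.shape != (n,):
            raise ValueError("B_in/bias dimensions must match A_rec")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def size(self) -> int:
        return self.A_rec.shape[0]

    @property
    def input_dim(self) -> int:
        return self.B_in.shape[1]


@dataclass
class ReadoutParams:
    """Bounded linear-tanh readout y = gain * tanh(C x + c)."""

    C_out: np.ndarray
    bias: np.ndarray
    output_gain: float = 1.0

    def __post_init__(self):
        self.C_out = np.atleast_2d(np.asarray(self.C_out, dtype=np.float64))
        self.bias = np.asarray(self.bias, dtype=np.float64)
        if self.bias.shape != (self.C_out.shape[0],):
            raise ValueError("readout bias must match output dimension")


@dataclass
class RNNParams:
    """Stacked recurrent layers plus the motor readout.

    The rates of one layer are the input of the next; the readout acts on
    the top layer.
    """

    layers: list[RNNLayerParams]
    readout: ReadoutParams

    def __post_init__(self):
        for lower, upper in zip(self.layers[:-1], self.layers[1:]):
            if upper.input_dim != lower.size:
                raise ValueError("layer input dim must match previous layer size")
        if self.readout.C_out.shape[1] != self.layers[-1].size:
            raise ValueError("readout must act on the top layer")

    @property
    def input_dim(self) -> int:
        return self.layers[0].input_dim

    @property
    def output_dim(self) -> int:
        return self.readout.C_out.shape[0]

    @property
    def n_association(self) -> int:
        """Total number of recurrent (association) neurons."""
        return sum(layer.size for layer in self.layers)

    def copy(self) -> "RNNParams":
        return RNNParams(
            layers=[RNNLayerParams(l.A_rec.copy(), l.B_in.copy(), l.bias.copy(), l.tau)
                    for l in self.layers],
            readout=ReadoutParams(self.readout.C_out.copy(), self.readout.bias.copy(),
                                  self.readout.output_gain),
        )

    # -- serialization ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write parameters to a .npz archive plus a JSON manifest."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        for i, l in enumerate(self.layers):
            arrays[f"layer{i}_A"] = l.A_rec
            arrays[f"layer{i}_B"] = l.B_in
            arrays[f"layer{i}_b"] = l.bias
        arrays["readout_C"] = self.readout.C_out
        arrays["readout_b"] = self.readout.bias
        np.savez(path, **arrays)
        manifest = {
            "layer_sizes": [l.size for l in self.layers],
            "taus": [l.tau for l in self.layers],
            "input_dim": self.input_dim,
            "output_dim": self.output_dim,
            "output_gain": self.readout.output_gain,
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "RNNParams":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            layers = [
                RNNLayerParams(z[f"layer{i}_A"], z[f"layer{i}_B"], z[f"layer{i}_b"], tau)
                for i, tau in enumerate(manifest["taus"])
            ]
            readout = ReadoutParams(z["readout_C"], z["readout_b"], manifest["output_gain"])
        return cls(layers, readout)


@dataclass
class RNNState:
    """Per-layer firing-rate vectors; components stay in (-1, 1)."""

    rates: list[np.ndarray]

    @classmethod
    def zeros(cls, params: RNNParams) -> "RNNState":
        return cls([np.zeros(l.size) for l in params.layers])


def rnn_step(state: RNNState, inp: np.ndarray, params: RNNParams,
             injections: list[np.ndarray] | None = None) -> tuple[RNNState, np.ndarray]:
    """One synchronous network tick.

    Per layer: ``x_t = tanh(A x_{t-1} + B u_t + b [+ injection])`` with the
    rates of each layer feeding the next; the readout then produces the
    bounded output. `injections` optionally adds an extra pre-activation
    current per layer (used for prosthetic stimulation).
    """
    u = np.atleast_1d(np.asarray(inp, dtype=np.float64))
    if u.shape != (params.input_dim,):
        raise ValueError(f"input shape {u.shape}, expected ({params.input_dim},)")
    new_rates: list[np.ndarray] = []
    for i, layer in enumerate(params.layers):
        pre = layer.A_rec @ state.rates[i] + layer.B_in @ u + layer.bias
        if injections is not None and injections[i] is not None:
            pre = pre + injections[i]
        u = np.tanh(pre)
        new_rates.append(u)
    out = params.readout.output_gain * np.tanh(params.readout.C_out @ u + params.readout.bias)
    return RNNState(new_rates), out


def continuous_rnn_derivative(v: np.ndarray, inp: np.ndarray,
                              layer: RNNLayerParams) -> np.ndarray:
    """Membrane-potential derivative (-v + A tanh(v) + B u + b) / tau."""
    v = np.asarray(v, dtype=np.float64)
    return (-v + layer.A_rec @ np.tanh(v) + layer.B_in @ np.atleast_1d(inp) + layer.bias) / layer.tau


def init_rnn(layer_sizes: list[int], input_dim: int, output_dim: int, seed: int,
             output_gain: float = 1.0, tau: float = 1.0,
             recurrent_scale: float = 1.0) -> RNNParams:
    """Reproducible random initialization.

    Recurrent weights are orthogonal (scaled by `recurrent_scale`), input
    and readout weights are Gaussian scaled by 1/sqrt(fan-in), biases zero.
    """
    if any(s < 1 for s in layer_sizes) or input_dim < 1 or output_dim < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    layers = []
    fan_in = input_dim
    for size in layer_sizes:
        q, r = np.linalg.qr(rng.standard_normal((size, size)))
        A = recurrent_scale * q * np.sign(np.diag(r))  # sign-fix for uniqueness
        B = rng.standard_normal((size, fan_in)) / np.sqrt(fan_in)
        layers.append(RNNLayerParams(A, B, np.zeros(size), tau))
        fan_in = size
    C = rng.standard_normal((output_dim, fan_in)) / np.sqrt(fan_in)
    readout = ReadoutParams(C, np.zeros(output_dim), output_gain)
    return RNNParams(layers, readout)


def particle_rnn(seed: int, obs_dim: int = 2, output_gain: float = 3.0) -> RNNParams:
    """Preset for the particle task: one 50-neuron association layer and a
    single motor neuron. The readout gain of 3 keeps the bounded motor
    command able to express the analytic controller's largest force on the
    unit start grid (max |K x| = 1 + sqrt(3) < 3)."""
    return init_rnn([50], obs_dim, 1, seed, output_gain=output_gain)


def pendulum_rnn(seed: int, obs_dim: int = 2, output_gain: float = 3.0) -> RNNParams:
    """Preset for pole balancing: two layers of 128 recurrent neurons and
    one motor neuron."""
    return init_rnn([128, 128], obs_dim, 1, seed, output_gain=output_gain)


class RNNController:
    """Stateful closed-loop adapter: resets rates to zero at episode start
    and maps one observation to one motor command per call."""

    def __init__(self, params: RNNParams):
        self.params = params
        self.state = RNNState.zeros(params)

    def reset(self) -> None:
        self.state = RNNState.zeros(self.params)

    def __call__(self, observation: np.ndarray) -> np.ndarray:
        self.state, out = rnn_step(self.state, observation, self.params)
        return out
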