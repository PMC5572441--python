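"""Spiking network description of the associative memory and back-end contract.

The trained binary matrix ``M`` is translated into a single feed-forward
layer: every output component is represented by ``omega`` conductance-based
LIF neurons, every input component by ``omega`` spike channels, and every
one-entry ``M_ij = 1`` by an all-to-all bundle of ``omega**2`` excitatory
synapses of identical weight ``w``.  Back-ends (the built-in simulator, or an
external adapter) are registered black boxes that receive a network
description plus input spike trains and return the recorded output trains.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codec import SpikeTrainSet

__all__ = [
    "NeuronParameters",
    "ParameterRange",
    "NetworkDescription",
    "build_network",
    "register_backend",
    "run_backend",
    "multiplex",
    "demultiplex",
]


@dataclass(frozen=True)
class NeuronParameters:
    """Conductance-based exponential-synapse LIF ("IfCondExp") parameters.

    Units: potentials mV, conductances nS, capacitance nF, times ms.  The
    synaptic weight ``w`` is the conductance increment applied per incoming
    spike and is shared by all synapses of the network.
    """

    v_rest: float = -80.0
    v_th: float = -57.0
    v_reset: float = -80.0
    tau_ref: float = 1.0
    g_leak: float = 20.0
    c_m: float = 0.2
    w: float = 10.0
    e_exc: float = 0.0
    tau_exc: float = 2.0

    def __post_init__(self) -> None:
        if not (self.v_reset <= self.v_rest < self.v_th):
            raise ValueError(
                f"need v_reset <= v_rest < v_th, got "
                f"({self.v_reset}, {self.v_rest}, {self.v_th})"
            )
        if self.g_leak <= 0 or self.c_m <= 0 or self.tau_exc <= 0 or self.tau_ref < 0:
            raise ValueError("conductances, capacitance and time constants must be positive")
        if self.w < 0:
            raise ValueError("synaptic weight must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant ``c_m / g_leak`` in ms."""
        return 1000.0 * self.c_m / self.g_leak

    def replace(self, **kwargs) -> "NeuronParameters":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ParameterRange:
    """Per-parameter bounds emulating a restricted hardware parameter space.

    ``bounds`` maps parameter names to ``(low, high)`` tuples; ``w_step``
    optionally quantises the synaptic weight to an equidistant grid (e.g. the
    4-bit weight discretisation of small analog systems).
    """

    bounds: dict
    w_step: float | None = None

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bound for {name!r} has low > high")

    def clamp(self, params: NeuronParameters) -> NeuronParameters:
        """Clamp parameters into range and quantise the weight. Idempotent."""
        updates = {}
        for name, (lo, hi) in self.bounds.items():
            value = getattr(params, name)
            updates[name] = min(max(value, lo), hi)
        if self.w_step is not None:
            w = updates.get("w", params.w)
            updates["w"] = round(w / self.w_step) * self.w_step
            if "w" in self.bounds:
                lo, hi = self.bounds["w"]
                updates["w"] = min(max(updates["w"], lo), hi)
        return params.replace(**updates)

    def contains(self, params: NeuronParameters) -> bool:
        return all(
            lo <= getattr(params, name) <= hi for name, (lo, hi) in self.bounds.items()
        )


@dataclass
class NetworkDescription:
    """Feed-forward network: input channels, one shared neuron type, synapses.

    ``synapses`` is a ``(pre_channel, post_neuron, weight_nS)`` triple list
    stored as three aligned arrays.  Index layout is population-blocked:
    logical output ``j`` owns neurons ``j*omega .. j*omega + omega - 1``.
    """

    n_inputs: int
    n_neurons: int
    params: NeuronParameters
    pre: np.ndarray
    post: np.ndarray
    weight: np.ndarray
    omega: int = 1

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "n_inputs": self.n_inputs,
            "n_neurons": self.n_neurons,
            "omega": self.omega,
            "neuron_parameters": self.params.as_dict(),
            "synapses": [
                [int(a), int(b), float(w)]
                for a, b, w in zip(self.pre, self.post, self.weight)
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "NetworkDescription":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        syn = np.asarray(doc["synapses"], dtype=float).reshape(-1, 3)
        return cls(
            n_inputs=int(doc["n_inputs"]),
            n_neurons=int(doc["n_neurons"]),
            params=NeuronParameters(**doc["neuron_parameters"]),
            pre=syn[:, 0].astype(np.int64),
            post=syn[:, 1].astype(np.int64),
            weight=syn[:, 2],
            omega=int(doc.get("omega", 1)),
        )


def build_network(
    M: np.ndarray, omega: int = 1, params: NeuronParameters | None = None
) -> NetworkDescription:
    """Build the network for a trained ``m x n`` memory matrix.

    Every one-entry contributes an all-to-all bundle of ``omega**2`` synapses
    between the entry's input channels and output neurons, all with weight
    ``params.w``.  The synapse list is a pure function of ``(M, omega,
    params)`` — rebuilding yields identical arrays.
    """
    if params is None:
        params = NeuronParameters()
    if omega < 1:
        raise ValueError("omega must be >= 1")
    M = np.asarray(M)
    m, n = M.shape
    rows, cols = np.nonzero(M)
    if len(rows) == 0:
        warnings.warn("memory matrix has no one-entries; network has zero synapses",
                      stacklevel=2)
    a = np.arange(omega)
    # bundle layout: for each entry, pre-offset varies slowest, post fastest
    pre = (rows[:, None] * omega + np.repeat(a, omega)[None, :]).ravel()
    post = (cols[:, None] * omega + np.tile(a, omega)[None, :]).ravel()
    weight = np.full(len(pre), float(params.w))
    return NetworkDescription(
        n_inputs=m * omega,
        n_neurons=n * omega,
        params=params,
        pre=pre.astype(np.int64),
        post=post.astype(np.int64),
        weight=weight,
        omega=omega,
    )


# --- black-box back-end registry -------------------------------------------

_BACKENDS: dict = {}


def register_backend(name: str, fn) -> None:
    """Register a back-end callable ``fn(net, inputs, **options) -> SpikeTrainSet``."""
    _BACKENDS[name] = fn


def _null_backend(net: NetworkDescription, inputs: SpikeTrainSet, **options) -> SpikeTrainSet:
    """Echo test double: returns the input trains unchanged (codec round trips)."""
    return SpikeTrainSet(trains=[t.copy() for t in inputs.trains], duration=inputs.duration)


register_backend("null", _null_backend)


def run_backend(
    net: NetworkDescription,
    inputs: SpikeTrainSet,
    backend: str = "builtin",
    options: dict | None = None,
):
    """Execute a network on a registered black-box back-end.

    Returns ``(outputs, wall_seconds)`` where ``outputs`` covers all
    ``net.n_neurons`` channels over the full input duration and
    ``wall_seconds`` is the wall-clock time around the back-end call
    (including its setup/teardown), the ``t`` of the efficiency measure.
    """
    if backend not in _BACKENDS:
        raise KeyError(
            f"unknown backend {backend!r}; registered: {sorted(_BACKENDS)}"
        )
    if inputs.n_channels > net.n_inputs:
        raise ValueError(
            f"input has {inputs.n_channels} channels but network declares {net.n_inputs}"
        )
    if inputs.n_channels < net.n_inputs:
        inputs = SpikeTrainSet(
            trains=list(inputs.trains)
            + [np.empty(0)] * (net.n_inputs - inputs.n_channels),
            duration=inputs.duration,
        )
    start = time.perf_counter()
    out = _BACKENDS[backend](net, inputs, **(options or {}))
    elapsed = time.perf_counter() - start
    if out.n_channels < net.n_neurons:
        out = SpikeTrainSet(
            trains=list(out.trains) + [np.empty(0)] * (net.n_neurons - out.n_channels),
            duration=out.duration,
        )
    return out, elapsed


# --- multiplexing of independent networks -----------------------------------


def multiplex(nets: list, inputs: list) -> tuple:
    """Merge independent networks into one description and one input set.

    Channel and neuron indices of the k-th network are offset by the totals of
    its predecessors; all networks must share neuron parameters.  Returns the
    combined ``(net, inputs, layout)`` where ``layout`` demultiplexes outputs.
    """
    if len(nets) != len(inputs):
        raise ValueError("need one input set per network")
    if not nets:
        raise ValueError("nothing to multiplex")
    params = nets[0].params
    for net in nets[1:]:
        if net.params != params:
            raise ValueError("multiplexed networks must share neuron parameters")
    in_off = np.cumsum([0] + [net.n_inputs for net in nets])
    out_off = np.cumsum([0] + [net.n_neurons for net in nets])
    pre = np.concatenate([net.pre + in_off[k] for k, net in enumerate(nets)])
    post = np.concatenate([net.post + out_off[k] for k, net in enumerate(nets)])
    weight = np.concatenate([net.weight for net in nets])
    duration = max(sp.duration for sp in inputs)
    trains: list[np.ndarray] = []
    for sp in inputs:
        trains.extend(np.asarray(t, dtype=float) for t in sp.trains)
    combined_net = NetworkDescription(
        n_inputs=int(in_off[-1]),
        n_neurons=int(out_off[-1]),
        params=params,
        pre=pre,
        post=post,
        weight=weight,
        omega=nets[0].omega,
    )
    combined_in = SpikeTrainSet(trains=trains, duration=duration)
    return combined_net, combined_in, out_off


def demultiplex(outputs: SpikeTrainSet, layout: np.ndarray) -> list:
    """Split combined back-end output back into per-network spike train sets."""
    return [
        SpikeTrainSet(
            trains=[outputs.trains[i] for i in range(layout[k], layout[k + 1])],
            duration=outputs.duration,
        )
        for k in range(len(layout) - 1)
    ]
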