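"""Reference software substrate: conductance-based LIF network simulation.

Implements the "IfCondExp" model — a leaky integrate-and-fire point neuron
with conductance-based synapses decaying exponentially:

    c_m dv/dt = g_leak (v_rest - v) + g_e (e_exc - v) + i_offset
    tau_exc dg_e/dt = -g_e,    spike arrival: g_e += w
    v >= v_th at a grid time -> output spike, v := v_reset, hold tau_ref

Two integrators are provided.  ``rkf45`` mirrors a high-quality reference
simulator: adaptive embedded Runge-Kutta-Fehlberg 4(5) sub-steps with an
absolute error target (default 1e-3) between the points of a synchronous
0.1 ms threshold/propagation grid.  ``euler`` is a deliberately naive
explicit step at the grid spacing itself (0.1 or 1.0 ms), without any of the
stability tricks production fixed-step integrators employ, so that the
accuracy cost of coarse fixed-step integration is observable in the
benchmark metrics.

Input spikes are delivered at the grid point ``ceil(t/dt)*dt`` — never
before their true time — matching synchronous spike-propagation semantics.
During the refractory period the membrane is clamped at ``v_reset`` (at grid
points) while synaptic conductance accumulates normally.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from ._kernels import simulate_grid
from .codec import SpikeTrainSet
from .network import NetworkDescription, NeuronParameters, register_backend

__all__ = ["IntegratorConfig", "SimulationResult", "simulate", "simulate_single_neuron"]


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration method and grid.

    method
        ``"euler"`` (fixed explicit step of ``dt``) or ``"rkf45"`` (adaptive
        sub-steps between grid points of spacing ``dt``).
    dt
        Threshold/spike-propagation grid spacing in ms (also the Euler step).
    abs_tol
        Absolute per-step error target of the rkf45 error estimate.
    """

    method: str = "rkf45"
    dt: float = 0.1
    abs_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.method not in ("euler", "rkf45"):
            raise ValueError(f"unknown integrator method {self.method!r}")
        if self.dt <= 0 or self.abs_tol <= 0:
            raise ValueError("dt and abs_tol must be positive")


@dataclass
class SimulationResult:
    """Spike trains, optional membrane traces at grid times, wall time."""

    spikes: SpikeTrainSet
    traces: np.ndarray | None
    times: np.ndarray | None
    wall_time: float


def _spike_steps(times: np.ndarray, dt: float) -> np.ndarray:
    # deliver at ceil(t/dt)*dt; tolerate float noise for times already on grid
    return np.ceil(times / dt - 1e-9).astype(np.int64)


def _run_events(
    params: NeuronParameters,
    n_neurons: int,
    ev_step: np.ndarray,
    ev_post: np.ndarray,
    ev_w_nS: np.ndarray,
    t_end: float,
    integ: IntegratorConfig,
    i_offset,
    record: bool,
) -> SimulationResult:
    n_steps = int(np.ceil(t_end / integ.dt - 1e-9))
    order = np.argsort(ev_step, kind="stable")
    ev_step = ev_step[order]
    ev_post = ev_post[order]
    ev_w = ev_w_nS[order] / 1000.0  # nS -> uS
    keep = ev_step < n_steps
    io = np.broadcast_to(np.asarray(i_offset, dtype=float), (n_neurons,)).copy()
    start = time.perf_counter()
    spike_t, spike_n, traces, ok = simulate_grid(
        n_neurons,
        n_steps,
        float(integ.dt),
        0 if integ.method == "euler" else 1,
        float(integ.abs_tol),
        params.v_rest,
        params.v_th,
        params.v_reset,
        params.tau_ref,
        params.g_leak / 1000.0,
        params.c_m,
        params.e_exc,
        params.tau_exc,
        io,
        ev_step[keep],
        ev_post[keep],
        ev_w[keep],
        record,
    )
    wall = time.perf_counter() - start
    if not ok:
        raise FloatingPointError(
            f"simulation state diverged (non-finite membrane state) with "
            f"{integ.method} step dt={integ.dt} ms"
        )
    trains = [spike_t[spike_n == i] for i in range(n_neurons)]
    times = np.arange(n_steps + 1) * integ.dt if record else None
    return SimulationResult(
        spikes=SpikeTrainSet(trains=trains, duration=t_end),
        traces=traces if record else None,
        times=times,
        wall_time=wall,
    )


def simulate(
    net: NetworkDescription,
    inputs: SpikeTrainSet,
    t_end: float | None = None,
    integ: IntegratorConfig | None = None,
    i_offset: float | np.ndarray = 0.0,
    record_traces: bool = False,
) -> SimulationResult:
    """Simulate a feed-forward network for the given input spike trains.

    ``i_offset`` is a constant offset current in nA, scalar or per neuron.
    """
    if integ is None:
        integ = IntegratorConfig()
    if inputs.n_channels != net.n_inputs:
        raise ValueError(
            f"input has {inputs.n_channels} channels, network expects {net.n_inputs}"
        )
    if t_end is None:
        t_end = inputs.duration
    last = max((t[-1] for t in inputs.trains if len(t)), default=0.0)
    if t_end < last:
        raise ValueError("t_end precedes the last input spike")
    # expand input spikes through the synapse fan-out into delivery events
    order = np.argsort(net.pre, kind="stable")
    pre_sorted = net.pre[order]
    post_sorted = net.post[order]
    w_sorted = net.weight[order]
    bounds = np.searchsorted(pre_sorted, np.arange(net.n_inputs + 1))
    steps_list, posts_list, ws_list = [], [], []
    for ch, train in enumerate(inputs.trains):
        lo, hi = bounds[ch], bounds[ch + 1]
        if hi == lo or len(train) == 0:
            continue
        steps = _spike_steps(np.asarray(train, dtype=float), integ.dt)
        k = hi - lo
        steps_list.append(np.repeat(steps, k))
        posts_list.append(np.tile(post_sorted[lo:hi], len(steps)))
        ws_list.append(np.tile(w_sorted[lo:hi], len(steps)))
    if steps_list:
        ev_step = np.concatenate(steps_list)
        ev_post = np.concatenate(posts_list)
        ev_w = np.concatenate(ws_list)
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_post = np.empty(0, dtype=np.int64)
        ev_w = np.empty(0)
    return _run_events(
        net.params, net.n_neurons, ev_step, ev_post, ev_w, t_end, integ,
        i_offset, record_traces,
    )


def simulate_single_neuron(
    params: NeuronParameters,
    input_spikes,
    t_end: float = 100.0,
    integ: IntegratorConfig | None = None,
    i_offset: float = 0.0,
):
    """Simulate one neuron fed by weighted input spikes.

    ``input_spikes`` is a sequence of ``(time_ms, weight_nS)`` pairs.
    Returns ``(spike_times, trace, grid_times)``; the membrane trace is
    always recorded.
    """
    if integ is None:
        integ = IntegratorConfig()
    if len(input_spikes):
        arr = np.asarray(input_spikes, dtype=float).reshape(-1, 2)
    else:
        arr = np.empty((0, 2))
    ev_step = _spike_steps(arr[:, 0], integ.dt)
    ev_post = np.zeros(len(arr), dtype=np.int64)
    ev_w = arr[:, 1]
    res = _run_events(
        params, 1, ev_step, ev_post, ev_w, t_end, integ,
        float(i_offset), True,
    )
    return res.spikes.trains[0], res.traces[:, 0], res.times


def _builtin_backend(
    net: NetworkDescription,
    inputs: SpikeTrainSet,
    integrator: IntegratorConfig | None = None,
    i_offset: float = 0.0,
    **_unused,
) -> SpikeTrainSet:
    res = simulate(net, inputs, integ=integrator, i_offset=i_offset)
    return res.spikes


register_backend("builtin", _builtin_backend)
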