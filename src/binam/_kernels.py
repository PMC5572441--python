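"""Numba inner loops of the reference conductance-based LIF simulator.

State per neuron: membrane potential ``v`` (mV) and excitatory conductance
``g`` (uS); parameters arrive pre-converted so that with capacitance in nF,
currents in nA and time in ms the membrane equation is simply
``dv/dt = (g_leak*(v_rest - v) + g*(e_exc - v) + i_offset) / c_m``.

Spike deliveries and threshold checks happen synchronously on the grid
``t_k = k*dt``; between grid points the state is advanced either by one naive
explicit Euler step (euler mode) or by adaptive embedded Runge-Kutta-Fehlberg
4(5) sub-steps (rkf45 mode).  During the refractory period the membrane is
clamped to ``v_reset`` at grid points while the conductance keeps evolving.
"""

import numpy as np
from numba import njit

# Fehlberg 4(5) tableau
_A21 = 1.0 / 4.0
_A31, _A32 = 3.0 / 32.0, 9.0 / 32.0
_A41, _A42, _A43 = 1932.0 / 2197.0, -7200.0 / 2197.0, 7296.0 / 2197.0
_A51, _A52, _A53, _A54 = 439.0 / 216.0, -8.0, 3680.0 / 513.0, -845.0 / 4104.0
_A61, _A62, _A63, _A64, _A65 = (
    -8.0 / 27.0,
    2.0,
    -3544.0 / 2565.0,
    1859.0 / 4104.0,
    -11.0 / 40.0,
)
_B41, _B43, _B44, _B45 = 25.0 / 216.0, 1408.0 / 2565.0, 2197.0 / 4104.0, -1.0 / 5.0
_B51, _B53, _B54, _B55, _B56 = (
    16.0 / 135.0,
    6656.0 / 12825.0,
    28561.0 / 56430.0,
    -9.0 / 50.0,
    2.0 / 55.0,
)


@njit(cache=True, fastmath=False)
def _grow(arr, n):
    out = np.empty(2 * len(arr), arr.dtype)
    out[:n] = arr[:n]
    return out


@njit(cache=True)
def _rkf45_interval(v, g, dt, gl, cm, vr, ee, taus, io, tol):
    """Advance one neuron by ``dt`` with adaptive embedded RKF 4(5) steps."""
    remaining = dt
    h = dt
    while remaining > 1e-12:
        if h > remaining:
            h = remaining
        # stage derivatives of (v, g)
        g1 = -g / taus
        v1 = (gl * (vr - v) + g * (ee - v) + io) / cm

        gv = g + h * _A21 * g1
        vv = v + h * _A21 * v1
        g2 = -gv / taus
        v2 = (gl * (vr - vv) + gv * (ee - vv) + io) / cm

        gv = g + h * (_A31 * g1 + _A32 * g2)
        vv = v + h * (_A31 * v1 + _A32 * v2)
        g3 = -gv / taus
        v3 = (gl * (vr - vv) + gv * (ee - vv) + io) / cm

        gv = g + h * (_A41 * g1 + _A42 * g2 + _A43 * g3)
        vv = v + h * (_A41 * v1 + _A42 * v2 + _A43 * v3)
        g4 = -gv / taus
        v4 = (gl * (vr - vv) + gv * (ee - vv) + io) / cm

        gv = g + h * (_A51 * g1 + _A52 * g2 + _A53 * g3 + _A54 * g4)
        vv = v + h * (_A51 * v1 + _A52 * v2 + _A53 * v3 + _A54 * v4)
        g5 = -gv / taus
        v5 = (gl * (vr - vv) + gv * (ee - vv) + io) / cm

        gv = g + h * (_A61 * g1 + _A62 * g2 + _A63 * g3 + _A64 * g4 + _A65 * g5)
        vv = v + h * (_A61 * v1 + _A62 * v2 + _A63 * v3 + _A64 * v4 + _A65 * v5)
        g6 = -gv / taus
        v6 = (gl * (vr - vv) + gv * (ee - vv) + io) / cm

        v_low = v + h * (_B41 * v1 + _B43 * v3 + _B44 * v4 + _B45 * v5)
        g_low = g + h * (_B41 * g1 + _B43 * g3 + _B44 * g4 + _B45 * g5)
        v_high = v + h * (_B51 * v1 + _B53 * v3 + _B54 * v4 + _B55 * v5 + _B56 * v6)
        g_high = g + h * (_B51 * g1 + _B53 * g3 + _B54 * g4 + _B55 * g5 + _B56 * g6)

        err = abs(v_high - v_low)
        eg = abs(g_high - g_low)
        if eg > err:
            err = eg
        if err <= tol or h <= 1e-6:
            v = v_high
            g = g_high
            remaining -= h
            if err > 0.0:
                fac = 0.9 * (tol / err) ** 0.2
                if fac > 5.0:
                    fac = 5.0
                if fac < 0.2:
                    fac = 0.2
                h *= fac
            else:
                h *= 5.0
        else:
            fac = 0.9 * (tol / err) ** 0.25
            if fac < 0.1:
                fac = 0.1
            h *= fac
    return v, g


@njit(cache=True)
def simulate_grid(
    n_neurons,
    n_steps,
    dt,
    method,  # 0 = euler, 1 = rkf45
    tol,
    v_rest,
    v_th,
    v_reset,
    tau_ref,
    g_leak,  # uS
    c_m,  # nF
    e_exc,
    tau_exc,
    i_offset,  # nA, per neuron
    ev_step,  # int64, sorted ascending
    ev_post,
    ev_w,  # uS
    record,
):
    v = np.full(n_neurons, v_rest)
    g = np.zeros(n_neurons)
    refr_end = np.full(n_neurons, -1.0e30)
    cap = 1024
    spike_t = np.empty(cap)
    spike_n = np.empty(cap, np.int64)
    n_spk = 0
    if record:
        traces = np.empty((n_steps + 1, n_neurons))
        traces[0] = v
    else:
        traces = np.empty((1, n_neurons))
    n_ev = len(ev_step)
    ptr = 0
    for k in range(n_steps):
        t_next = (k + 1) * dt
        while ptr < n_ev and ev_step[ptr] == k:
            g[ev_post[ptr]] += ev_w[ptr]
            ptr += 1
        for i in range(n_neurons):
            gi = g[i]
            vi = v[i]
            io = i_offset[i]
            if gi < 1e-14 and io == 0.0 and abs(vi - v_rest) < 1e-10:
                v[i] = v_rest
                g[i] = 0.0
            elif method == 0:
                dv = (g_leak * (v_rest - vi) + gi * (e_exc - vi) + io) / c_m
                v[i] = vi + dt * dv
                gn = gi - dt * gi / tau_exc
                g[i] = gn if gn > 0.0 else 0.0
            else:
                v[i], g[i] = _rkf45_interval(
                    vi, gi, dt, g_leak, c_m, v_rest, e_exc, tau_exc, io, tol
                )
            if t_next <= refr_end[i] + 1e-9:
                v[i] = v_reset
            elif v[i] >= v_th:
                if n_spk == cap:
                    spike_t = _grow(spike_t, n_spk)
                    spike_n = _grow(spike_n, n_spk)
                    cap *= 2
                spike_t[n_spk] = t_next
                spike_n[n_spk] = i
                n_spk += 1
                v[i] = v_reset
                refr_end[i] = t_next + tau_ref
        if record:
            traces[k + 1] = v
    ok = True
    for i in range(n_neurons):
        if not (np.isfinite(v[i]) and np.isfinite(g[i])):
            ok = False
    return spike_t[:n_spk], spike_n[:n_spk], traces, ok
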