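"""Independent reference implementations used as test oracles.

Everything here is written as plain scalar Python, structured
differently from the vectorized simulator: per-synapse state instead of
aggregated conductances, explicit event lists instead of ring buffers,
closed-form two-point plasticity updates instead of per-step decay
factors where possible.  These implementations are deliberately slow.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# analytic LIF

def lif_steady_state(g_L, V_L, g_E, V_E, g_I, V_I):
    """Conductance-weighted steady-state membrane potential (mV)."""
    return (g_L * V_L + g_E * V_E + g_I * V_I) / (g_L + g_E + g_I)


def lif_isi(params, g_E, g_I=0.0):
    """Analytic inter-spike interval (ms) of a noise-free LIF under
    constant conductances: refractory period plus the exponential
    charging time from reset to threshold."""
    g_tot = params.leak_conductance + g_E + g_I
    v_inf = lif_steady_state(params.leak_conductance, params.leak_reversal,
                             g_E, params.excitatory_reversal,
                             g_I, params.inhibitory_reversal)
    if v_inf <= params.threshold:
        return math.inf
    tau = 1000.0 * params.membrane_capacitance / g_tot  # nF/nS -> s -> ms
    t_charge = tau * math.log((params.reset - v_inf)
                              / (params.threshold - v_inf))
    return params.refractory + t_charge


# ---------------------------------------------------------------------------
# event-driven short-term plasticity

def tm_plasticity_events(spike_times, U, tau_u, tau_x):
    """Utilization, resources and release peaks at a list of spike times.

    Closed-form relaxation between spikes (u -> U with tau_u, x -> 1 with
    tau_x), then the per-spike update: u increments first, the peak u*x
    is released, and the released fraction leaves the resource pool.
    Returns a list of (u_after, x_after, peak) per spike.
    """
    u, x = U, 1.0
    t_prev = None
    out = []
    for t in spike_times:
        if t_prev is not None:
            dt = t - t_prev
            u = U + (u - U) * math.exp(-dt / tau_u)
            x = 1.0 + (x - 1.0) * math.exp(-dt / tau_x)
        u = u + U * (1.0 - u)
        peak = u * x
        x = x - peak
        out.append((u, x, peak))
        t_prev = t
    return out


def mean_synaptic_activity_regular(rate_khz, tau_s, n_spikes=2000):
    """Long-run time average of a set-to-peak / exponential-decay synapse
    driven by a regular spike train of ``rate_khz`` (event-driven)."""
    if rate_khz <= 0:
        return 0.0
    isi = 1.0 / rate_khz
    # after many spikes s just before a spike is periodic: s_peak = 1
    # (constant synapse); average over one ISI of exp decay from 1
    return (tau_s / isi) * (1.0 - math.exp(-isi / tau_s))


# ---------------------------------------------------------------------------
# event-driven scalar network reference

def simulate_reference(net, duration, seed=None, frozen_plasticity=False):
    """Scalar event-driven reference simulation of a network instance.

    Noise-free (``seed`` unused; kept for signature parity).  Returns
    ``(spike_times, spike_neurons)`` as lists, spikes timestamped at the
    end of the integration step in which threshold was crossed.
    """
    cfg = net.config
    dt = cfg.dt
    n = net.n_total
    protocol = cfg.protocol

    # per-neuron constants
    P = {}
    for label in net.pop_order:
        sl = net.pop_slice[label]
        pop = cfg.populations[label]
        for i in range(sl.start, sl.stop):
            P[i] = (pop.neuron, pop.bias_conductance, label)

    # per-synapse lists: (pre, post, delay_steps, weight, kind)
    synapses = []
    for cls in net.classes:
        post0 = net.pop_slice[cls.post_pop].start
        n_post, k = cls.pre_index.shape
        for pi in range(n_post):
            for j in range(k):
                d = max(1, int(round(cls.delay[pi, j] / dt)))
                synapses.append((int(cls.pre_index[pi, j]), post0 + pi,
                                 d, cls.weight, cls.kind))

    esE = math.exp(-dt / cfg.tau_s_exc)
    esI = math.exp(-dt / cfg.tau_s_inh)
    pF = cfg.plasticity["facilitation"]
    pD = cfg.plasticity["depression"]
    euF, exF = math.exp(-dt / pF.tau_u), math.exp(-dt / pF.tau_x)
    euD, exD = math.exp(-dt / pD.tau_u), math.exp(-dt / pD.tau_x)

    V = [P[i][0].leak_reversal for i in range(n)]
    ref = [0] * n
    uF = [pF.U_rest] * n
    xF = [1.0] * n
    uD = [pD.U_rest] * n
    xD = [1.0] * n
    s_syn = [0.0] * len(synapses)           # delayed per-synapse activity
    pending = []                             # (due_step, syn_index, peak)

    from reorgnet.spiking import external_conductance

    n_steps = int(round(duration / dt))
    spike_times, spike_neurons = [], []

    for step in range(n_steps):
        t = step * dt
        # deliver due synapse updates (set delayed activity to peak)
        still = []
        for due, si, peak in pending:
            if due == step:
                s_syn[si] = peak
            else:
                still.append((due, si, peak))
        pending = still

        # conductances per neuron
        gE = [0.0] * n
        gI = [0.0] * n
        for si, (pre, post, d, w, kind) in enumerate(synapses):
            if s_syn[si] != 0.0:
                if kind == "inhibitory":
                    gI[post] += w * s_syn[si]
                else:
                    gE[post] += w * s_syn[si]

        spiking = []
        for i in range(n):
            p, bias, label = P[i]
            if ref[i] > 0:
                V[i] = p.reset
                ref[i] -= 1
                continue
            g_E = gE[i] + bias + external_conductance(protocol, label, t)
            g_I = gI[i]
            c_ms = p.membrane_capacitance * 1e3

            def f(v):
                return (-p.leak_conductance * (v - p.leak_reversal)
                        - g_E * (v - p.excitatory_reversal)
                        - g_I * (v - p.inhibitory_reversal)) / c_ms

            k1 = f(V[i])
            k2 = f(V[i] + 0.5 * dt * k1)
            k3 = f(V[i] + 0.5 * dt * k2)
            k4 = f(V[i] + dt * k3)
            v_new = V[i] + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if v_new >= p.threshold:
                spiking.append(i)
                V[i] = p.reset
                ref[i] = int(round(p.refractory / dt))
            else:
                V[i] = v_new

        # decay all synaptic state to the end of the step
        for si, (pre, post, d, w, kind) in enumerate(synapses):
            s_syn[si] *= esI if kind == "inhibitory" else esE
        if not frozen_plasticity:
            for i in range(n):
                uF[i] = pF.U_rest + (uF[i] - pF.U_rest) * euF
                xF[i] = 1.0 + (xF[i] - 1.0) * exF
                uD[i] = pD.U_rest + (uD[i] - pD.U_rest) * euD
                xD[i] = 1.0 + (xD[i] - 1.0) * exD

        # spike bookkeeping (at t + dt) and event scheduling
        for i in spiking:
            spike_times.append(t + dt)
            spike_neurons.append(i)
            if frozen_plasticity:
                peakF = pF.U_rest
                peakD = pD.U_rest
            else:
                uF[i] = uF[i] + pF.U_rest * (1.0 - uF[i])
                peakF = uF[i] * xF[i]
                xF[i] = xF[i] - peakF
                uD[i] = uD[i] + pD.U_rest * (1.0 - uD[i])
                peakD = uD[i] * xD[i]
                xD[i] = xD[i] - peakD
            for si, (pre, post, d, w, kind) in enumerate(synapses):
                if pre != i:
                    continue
                peak = {"facilitation": peakF, "depression": peakD,
                        "constant": 1.0, "inhibitory": 1.0}[kind]
                pending.append((step + 1 + d, si, peak))

    return spike_times, spike_neurons
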