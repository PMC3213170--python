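"""Spiking simulation of the reorganizable attractor network.

Noisy leaky integrate-and-fire neurons with conductance-based synapses
and Tsodyks--Markram short-term plasticity.  The membrane equation

    C_m dV/dt = -g_L (V - V_L) - g_E (V - V_E) - g_I (V - V_I)

is integrated with fixed-step classical Runge--Kutta (dt = 0.1 ms by
default), conductances held constant within a step; an independent
normal deviate of standard deviation ``noise_sigma * sqrt(dt)`` is added
to each non-refractory membrane potential every step.  Threshold
crossings are checked after each step: the neuron spikes, is reset and
held at the reset potential for its refractory period.

Each excitatory neuron owns three synaptic-activity variables (one per
synapse kind: facilitation, depression, constant) shared by all of its
efferent synapses of that kind; interneurons own one inhibitory
activity.  A presynaptic spike sets the activity to its current peak
(u * x for plastic kinds after the utilization update, 1 for constant
kinds), from which it decays exponentially.  Delayed delivery is exact:
every synapse deposits ``weight * (peak - s_before)`` onto its target's
aggregated conductance one transmission delay after the spike, and the
aggregate decays with the same time constant as the activities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (ACTION_ASSEMBLIES, ALL_POPS, ASSEMBLY_EDGES, EXC_POPS,
                     GOAL_ASSEMBLIES, INH_POP, NetworkConfig, StimulusProtocol,
                     validate_config)
from .network import NetworkInstance, build_network

KIND_CODE = {"facilitation": 0, "depression": 1, "constant": 2, "inhibitory": 3}
PLASTIC_KINDS = ("facilitation", "depression")


class SimulationError(RuntimeError):
    """Numerical failure (non-finite state) during a simulation."""


# ---------------------------------------------------------------------------
# elementary updates (shared by the vectorized simulator and by tests)

def rk4_membrane(V, g_L, V_L, g_E, V_E, g_I, V_I, C_m, dt):
    """One classical Runge--Kutta step of the membrane equation.

    Conductances are held constant over the step.  Works elementwise on
    arrays or scalars.  ``C_m`` is in nF and conductances in nS, so C/g
    is in seconds; the factor 1000 converts the rate to mV/ms.
    """
    c_ms = C_m * 1e3  # nF -> nS * ms

    def f(v):
        return (-g_L * (v - V_L) - g_E * (v - V_E) - g_I * (v - V_I)) / c_ms

    k1 = f(V)
    k2 = f(V + 0.5 * dt * k1)
    k3 = f(V + 0.5 * dt * k2)
    k4 = f(V + dt * k3)
    return V + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def apply_spike_plasticity(u, x, U):
    """Per-spike short-term-plasticity update.

    The utilization is incremented first, the release peak is the product
    of the updated utilization and the available resources, and the
    released fraction is then subtracted from the resources:

        u <- u + U (1 - u);   peak = u x;   x <- x - u x

    Returns ``(u, x, peak)``; all outputs stay in [0, 1] for inputs in
    [0, 1].  Works elementwise.
    """
    u = u + U * (1.0 - u)
    peak = u * x
    x = x - peak
    return u, x, peak


@dataclass
class NeuronState:
    """Membrane state of a neuron group."""

    membrane_potential: np.ndarray   # mV
    refractory_remaining: np.ndarray  # integration steps left


def membrane_step(state: NeuronState, g_E, g_I, params, dt, rng=None):
    """Advance a neuron group one step; returns ``(state, spiking_indices)``.

    ``params`` is a :class:`~reorgnet.config.NeuronParams`.  Noise is
    drawn from ``rng`` (omitted when ``rng`` is None or ``noise_sigma``
    is 0).  Used directly by tests and by the uncoupled-pool rate
    sampler; the network simulator applies the same arithmetic inline.
    """
    V = state.membrane_potential
    ref = state.refractory_remaining
    active = ref == 0
    V_new = rk4_membrane(V, params.leak_conductance, params.leak_reversal,
                         g_E, params.excitatory_reversal,
                         g_I, params.inhibitory_reversal,
                         params.membrane_capacitance, dt)
    V_new = np.where(active, V_new, params.reset)
    if rng is not None and params.noise_sigma > 0:
        V_new = V_new + np.where(
            active,
            params.noise_sigma * np.sqrt(dt) * rng.standard_normal(V.shape),
            0.0)
    if not np.all(np.isfinite(V_new)):
        raise SimulationError("non-finite membrane potential")
    spiking = np.flatnonzero(active & (V_new >= params.threshold))
    ref_steps = int(round(params.refractory / dt))
    V_new[spiking] = params.reset
    ref = np.maximum(ref - 1, 0)
    ref[spiking] = ref_steps
    state.membrane_potential = V_new
    state.refractory_remaining = ref
    return state, spiking


# ---------------------------------------------------------------------------
# stimulus

def external_conductance(protocol: StimulusProtocol, pop: str, t: float) -> float:
    """External input conductance (nS) onto population ``pop`` at time ``t``."""
    if pop == INH_POP:
        return 0.0
    g = 0.0
    t0 = protocol.goal_display_onset
    if t >= t0 and protocol.activation_amplitude > 0:
        ramp = protocol.activation_ramp
        frac = 1.0 if ramp <= 0 else min((t - t0) / ramp, 1.0)
        g += protocol.activation_amplitude * frac
    if (protocol.sensory_amplitude > 0
            and pop in GOAL_ASSEMBLIES[protocol.sensory_target]
            and t0 <= t < t0 + protocol.sensory_width):
        g += protocol.sensory_amplitude
    if (protocol.perturbation_amplitude > 0
            and pop in ACTION_ASSEMBLIES[protocol.perturbation_target]):
        p0 = t0 + protocol.perturbation_onset
        if p0 <= t < p0 + protocol.perturbation_width:
            g += protocol.perturbation_amplitude
    return g


# ---------------------------------------------------------------------------
# recording containers

@dataclass
class TrialTrace:
    """Recorded time course of one trial.

    Population rates are kernel-smoothed spike densities in Hz; synaptic
    summaries are population means of the per-neuron variables; assembly
    efficacies follow the peak-conductance definition (summed weight
    times the connection-weighted mean release peak).
    """

    config: NetworkConfig
    seed: int
    time: np.ndarray                     # ms, record grid
    rates: dict                          # pop -> Hz
    mean_u: dict                         # (pop, kind) -> array
    mean_x: dict
    mean_s: dict                         # (pop, kind) -> array, kind incl. 'constant'
    efficacy: dict                       # assembly label -> nS
    stimulus: dict                       # pop -> nS
    spike_times: np.ndarray              # ms
    spike_neurons: np.ndarray            # global indices
    pop_slice: dict = field(default_factory=dict)

    @property
    def readout(self) -> dict:
        """Read-out activities: A1 = rate(A) + rate(D), A2 = rate(B) + rate(C)."""
        return {
            "A1": self.rates["A"] + self.rates["D"],
            "A2": self.rates["B"] + self.rates["C"],
        }

    def selected_action(self, factor: float = 2.0, hold_ms: float = 200.0):
        """Action selected by the end of the trial.

        The selected action is the one whose read-out exceeds ``factor``
        times the other continuously through the final ``hold_ms`` of the
        trial (the network has converged to that action attractor);
        ``None`` if neither read-out is dominant at the end.
        """
        ro = self.readout
        dt = float(self.time[1] - self.time[0])
        need = max(1, int(round(hold_ms / dt)))
        for label, other in (("A1", "A2"), ("A2", "A1")):
            dominant = ro[label] > factor * ro[other] + 1e-12
            if dominant.size >= need and bool(np.all(dominant[-need:])):
                return label
        return None

    def to_frame(self):
        """Long-format table of the recorded traces (pandas DataFrame)."""
        import pandas as pd
        cols = {"time_ms": self.time}
        for p in self.rates:
            cols[f"rate_{p}_hz"] = self.rates[p]
        for (p, k), v in self.mean_u.items():
            cols[f"u_{k[0]}_{p}"] = v
        for (p, k), v in self.mean_x.items():
            cols[f"x_{k[0]}_{p}"] = v
        for (p, k), v in self.mean_s.items():
            cols[f"s_{k[0]}_{p}"] = v
        for a, v in self.efficacy.items():
            cols[f"efficacy_{a.replace('&', '')}_ns"] = v
        for p, v in self.stimulus.items():
            cols[f"stim_{p}_ns"] = v
        return pd.DataFrame(cols)

    def spikes_frame(self):
        import pandas as pd
        pops = np.empty(len(self.spike_neurons), dtype=object)
        for label, sl in self.pop_slice.items():
            mask = (self.spike_neurons >= sl.start) & (self.spike_neurons < sl.stop)
            pops[mask] = label
        return pd.DataFrame({
            "time_ms": self.spike_times,
            "population": pops,
            "neuron": self.spike_neurons,
        })


def _longest_true_run(mask: np.ndarray) -> int:
    best = run = 0
    for v in mask:
        run = run + 1 if v else 0
        best = max(best, run)
    return best


def _first_sustained(mask: np.ndarray, need: int):
    """Index of the first run of ``need`` consecutive True values."""
    if need <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if idx.size else None
    run = 0
    for i, v in enumerate(mask):
        run = run + 1 if v else 0
        if run >= need:
            return i - need + 1
    return None


def population_rate(spike_times, pop_size: int, kernel_width: float,
                    time_grid: np.ndarray) -> np.ndarray:
    """Kernel-smoothed population firing rate in Hz.

    Spikes are binned on ``time_grid`` (ms) and convolved with a
    unit-mass Gaussian of standard deviation ``kernel_width`` ms, so the
    time integral of ``rate * pop_size`` equals the spike count.
    """
    if kernel_width <= 0:
        raise ValueError("kernel_width must be > 0")
    dt = float(time_grid[1] - time_grid[0])
    edges = np.concatenate([time_grid - dt / 2, [time_grid[-1] + dt / 2]])
    counts, _ = np.histogram(spike_times, bins=edges)
    half = int(np.ceil(4 * kernel_width / dt))
    support = np.arange(-half, half + 1) * dt
    kernel = np.exp(-0.5 * (support / kernel_width) ** 2)
    kernel /= kernel.sum()
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    # counts per bin -> rate per neuron: spikes / (pop_size * dt[ms]) * 1000
    return smoothed * 1000.0 / (pop_size * dt)


# ---------------------------------------------------------------------------
# the vectorized network simulator

class SpikingSimulator:
    """Vectorized simulator for one network realization."""

    def __init__(self, net: NetworkInstance):
        self.net = net
        cfg = net.config
        self.cfg = cfg
        self.dt = cfg.dt
        n = net.n_total
        self.n = n

        # per-neuron constants
        self.C_m = np.empty(n)
        self.g_L = np.empty(n)
        self.V_L = np.empty(n)
        self.V_th = np.empty(n)
        self.V_reset = np.empty(n)
        self.V_E = np.empty(n)
        self.V_I = np.empty(n)
        self.sigma = np.empty(n)
        self.bias = np.empty(n)
        self.ref_steps = np.empty(n, dtype=np.int64)
        for label in net.pop_order:
            sl = net.pop_slice[label]
            pop = cfg.populations[label]
            p = pop.neuron
            self.C_m[sl] = p.membrane_capacitance
            self.g_L[sl] = p.leak_conductance
            self.V_L[sl] = p.leak_reversal
            self.V_th[sl] = p.threshold
            self.V_reset[sl] = p.reset
            self.V_E[sl] = p.excitatory_reversal
            self.V_I[sl] = p.inhibitory_reversal
            self.sigma[sl] = p.noise_sigma
            self.bias[sl] = pop.bias_conductance
            self.ref_steps[sl] = int(round(p.refractory / self.dt))

        self.exc_mask = np.zeros(n, dtype=bool)
        for p in EXC_POPS:
            self.exc_mask[net.pop_slice[p]] = True

        self._compile_synapses()
        self._compile_efficacy()

    # -- synapse compilation ------------------------------------------------
    def _compile_synapses(self):
        net, dt = self.net, self.dt
        pre_all, post_all, dstep_all, w_all, kind_all = [], [], [], [], []
        for cls in net.classes:
            post_sl = net.pop_slice[cls.post_pop]
            n_post, k = cls.pre_index.shape
            post = np.repeat(np.arange(post_sl.start, post_sl.stop), k)
            pre_all.append(cls.pre_index.ravel())
            post_all.append(post)
            dstep_all.append(np.maximum(np.round(cls.delay / dt), 1).astype(np.int64).ravel())
            w_all.append(np.full(n_post * k, cls.weight))
            kind_all.append(np.full(n_post * k, KIND_CODE[cls.kind], dtype=np.int8))
        pre = np.concatenate(pre_all)
        order = np.argsort(pre, kind="stable")
        self.syn_pre = pre[order]
        self.syn_post = np.concatenate(post_all)[order]
        self.syn_dstep = np.concatenate(dstep_all)[order]
        self.syn_w = np.concatenate(w_all)[order]
        self.syn_kind = np.concatenate(kind_all)[order]
        counts = np.bincount(self.syn_pre, minlength=self.n)
        self.eff_ptr = np.concatenate([[0], np.cumsum(counts)])
        self.max_dstep = int(self.syn_dstep.max()) if self.syn_dstep.size else 1

    def _compile_efficacy(self):
        # assembly -> list of (kind_code, summed_weight, multiplicity/N_post
        # over the presynaptic population) for its two directed edges
        self.efficacy_terms = {}
        net = self.net
        for label, edges in ASSEMBLY_EDGES.items():
            terms = []
            for pre_pop, post_pop in edges:
                for cls in net.classes:
                    if cls.pre_pop == pre_pop and cls.post_pop == post_pop:
                        pre_sl = net.pop_slice[pre_pop]
                        mult = np.bincount(cls.pre_index.ravel() - pre_sl.start,
                                           minlength=pre_sl.stop - pre_sl.start)
                        n_post = cls.pre_index.shape[0]
                        terms.append((KIND_CODE[cls.kind], cls.weight,
                                      pre_sl, mult / n_post))
            self.efficacy_terms[label] = terms

    # -- state --------------------------------------------------------------
    def _init_state(self):
        cfg, n = self.cfg, self.n
        st = {}
        st["V"] = self.V_L.copy()
        st["ref"] = np.zeros(n, dtype=np.int64)
        st["sF"] = np.zeros(n)
        st["sD"] = np.zeros(n)
        st["sC"] = np.zeros(n)
        st["sI"] = np.zeros(n)
        UF = cfg.plasticity["facilitation"].U_rest
        UD = cfg.plasticity["depression"].U_rest
        st["uF"] = np.full(n, UF)
        st["xF"] = np.ones(n)
        st["uD"] = np.full(n, UD)
        st["xD"] = np.ones(n)
        st["gsE"] = np.zeros(n)   # aggregated delayed excitatory conductance
        st["gsI"] = np.zeros(n)
        return st

    def _peak(self, st, code):
        """Current release peak per presynaptic neuron for a kind code."""
        if code == KIND_CODE["facilitation"]:
            return st["uF"] * st["xF"]
        if code == KIND_CODE["depression"]:
            return st["uD"] * st["xD"]
        return np.ones(self.n)

    # -- main loop ----------------------------------------------------------
    def run(self, seed: int, protocol: StimulusProtocol | None = None,
            record_stride: float = 1.0, frozen_plasticity: bool = False,
            kernel_width: float = 50.0, duration: float | None = None,
            collect_spikes: bool = True) -> TrialTrace:
        """Simulate one trial.

        Parameters
        ----------
        seed
            Noise seed for this trial (connectivity comes from the
            network instance).
        record_stride
            Sampling interval of the recorded traces, ms.
        frozen_plasticity
            Clamp u and x at rest (no-plasticity control).
        kernel_width
            Gaussian width (ms) of the spike-density rate estimate.
        """
        cfg, net, dt, n = self.cfg, self.net, self.dt, self.n
        protocol = protocol or cfg.protocol
        T = duration if duration is not None else protocol.trial_duration
        n_steps = int(round(T / dt))
        stride = max(1, int(round(record_stride / dt)))
        n_rec = n_steps // stride + 1

        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
        st = self._init_state()

        plas = cfg.plasticity
        euF = np.exp(-dt / plas["facilitation"].tau_u)
        exF = np.exp(-dt / plas["facilitation"].tau_x)
        euD = np.exp(-dt / plas["depression"].tau_u)
        exD = np.exp(-dt / plas["depression"].tau_x)
        UF = plas["facilitation"].U_rest
        UD = plas["depression"].U_rest
        esE = np.exp(-dt / cfg.tau_s_exc)
        esI = np.exp(-dt / cfg.tau_s_inh)

        L = self.max_dstep + 2
        buf_E = np.zeros((L, n))
        buf_I = np.zeros((L, n))

        exc = self.exc_mask
        sq_dt = np.sqrt(dt)
        any_noise = np.any(self.sigma > 0)

        pop_items = [(p, net.pop_slice[p]) for p in net.pop_order]
        ext_pops = [p for p in net.pop_order if p in EXC_POPS]

        # recording buffers
        rec_t = np.empty(n_rec)
        rec_counts = {p: np.zeros(n_rec) for p, _ in pop_items}
        rec_u = {(p, k): np.empty(n_rec) for p in EXC_POPS for k in PLASTIC_KINDS}
        rec_x = {(p, k): np.empty(n_rec) for p in EXC_POPS for k in PLASTIC_KINDS}
        rec_s = {(p, k): np.empty(n_rec)
                 for p in EXC_POPS for k in ("facilitation", "depression", "constant")}
        rec_s.update({(INH_POP, "inhibitory"): np.empty(n_rec)})
        rec_eff = {a: np.empty(n_rec) for a in ASSEMBLY_EDGES}
        rec_stim = {p: np.empty(n_rec) for p, _ in pop_items}
        spike_t_chunks, spike_i_chunks = [], []

        kind_codes = (KIND_CODE["facilitation"], KIND_CODE["depression"],
                      KIND_CODE["constant"], KIND_CODE["inhibitory"])

        def record(idx, t, counts_since):
            rec_t[idx] = t
            for p, sl in pop_items:
                rec_counts[p][idx] = counts_since.get(p, 0.0)
            for p in EXC_POPS:
                sl = net.pop_slice[p]
                rec_u[(p, "facilitation")][idx] = st["uF"][sl].mean()
                rec_x[(p, "facilitation")][idx] = st["xF"][sl].mean()
                rec_u[(p, "depression")][idx] = st["uD"][sl].mean()
                rec_x[(p, "depression")][idx] = st["xD"][sl].mean()
                rec_s[(p, "facilitation")][idx] = st["sF"][sl].mean()
                rec_s[(p, "depression")][idx] = st["sD"][sl].mean()
                rec_s[(p, "constant")][idx] = st["sC"][sl].mean()
            rec_s[(INH_POP, "inhibitory")][idx] = st["sI"][net.pop_slice[INH_POP]].mean()
            for a, terms in self.efficacy_terms.items():
                # mean over assembly neurons of their summed within-assembly
                # peak conductance; every neuron has exactly one incoming
                # within-assembly class, so average the per-edge means
                val = 0.0
                for code, w, pre_sl, mult in terms:
                    peak = self._peak(st, code)[pre_sl]
                    val += w * float(mult @ peak)
                rec_eff[a][idx] = val / len(terms)
            for p, sl in pop_items:
                rec_stim[p][idx] = external_conductance(protocol, p, t)

        record(0, 0.0, {})
        rec_idx = 1

        g_ext = np.zeros(n)
        counts_acc = {p: 0.0 for p, _ in pop_items}

        for step in range(n_steps):
            t = step * dt
            slot = step % L
            # deliver due deposits
            st["gsE"] += buf_E[slot]
            st["gsI"] += buf_I[slot]
            buf_E[slot] = 0.0
            buf_I[slot] = 0.0

            # external input (per population, piecewise constant over dt)
            for p in ext_pops:
                g_ext[net.pop_slice[p]] = external_conductance(protocol, p, t)

            g_E = st["gsE"] + self.bias + g_ext
            g_I = st["gsI"]

            # membrane update (RK4, conductances frozen within the step)
            V = st["V"]
            active = st["ref"] == 0
            V_new = rk4_membrane(V, self.g_L, self.V_L, g_E, self.V_E,
                                 g_I, self.V_I, self.C_m, dt)
            V_new = np.where(active, V_new, self.V_reset)
            if any_noise:
                noise = self.sigma * sq_dt * rng.standard_normal(n)
                V_new = np.where(active, V_new + noise, V_new)

            spiking = np.flatnonzero(active & (V_new >= self.V_th))
            V_new[spiking] = self.V_reset[spiking]
            st["ref"] = np.maximum(st["ref"] - 1, 0)
            st["ref"][spiking] = self.ref_steps[spiking]
            st["V"] = V_new

            # decay synaptic variables to the end of the step
            st["sF"] *= esE
            st["sD"] *= esE
            st["sC"] *= esE
            st["sI"] *= esI
            st["gsE"] *= esE
            st["gsI"] *= esI
            if not frozen_plasticity:
                st["uF"] = UF + (st["uF"] - UF) * euF
                st["xF"] = 1.0 + (st["xF"] - 1.0) * exF
                st["uD"] = UD + (st["uD"] - UD) * euD
                st["xD"] = 1.0 + (st["xD"] - 1.0) * exD

            if spiking.size:
                t_spk = t + dt
                if collect_spikes:
                    spike_t_chunks.append(np.full(spiking.size, t_spk))
                    spike_i_chunks.append(spiking.copy())
                for p, sl in pop_items:
                    c = np.count_nonzero((spiking >= sl.start) & (spiking < sl.stop))
                    if c:
                        counts_acc[p] += c

                exc_spk = spiking[exc[spiking]]
                inh_spk = spiking[~exc[spiking]]
                deltas = {}
                if exc_spk.size:
                    if frozen_plasticity:
                        # u, x clamped at rest: every spike releases U * 1
                        pF = np.full(exc_spk.size, UF)
                        pD = np.full(exc_spk.size, UD)
                    else:
                        uF, xF, pF = apply_spike_plasticity(
                            st["uF"][exc_spk], st["xF"][exc_spk], UF)
                        uD, xD, pD = apply_spike_plasticity(
                            st["uD"][exc_spk], st["xD"][exc_spk], UD)
                        st["uF"][exc_spk] = uF
                        st["xF"][exc_spk] = xF
                        st["uD"][exc_spk] = uD
                        st["xD"][exc_spk] = xD
                    dF = pF - st["sF"][exc_spk]
                    dD = pD - st["sD"][exc_spk]
                    dC = 1.0 - st["sC"][exc_spk]
                    st["sF"][exc_spk] = pF
                    st["sD"][exc_spk] = pD
                    st["sC"][exc_spk] = 1.0
                    for j, ddF, ddD, ddC in zip(exc_spk, dF, dD, dC):
                        deltas[j] = (ddF, ddD, ddC, 0.0)
                if inh_spk.size:
                    dI = 1.0 - st["sI"][inh_spk]
                    st["sI"][inh_spk] = 1.0
                    for j, ddI in zip(inh_spk, dI):
                        deltas[j] = (0.0, 0.0, 0.0, ddI)

                # schedule delayed deposits
                for j, dvals in deltas.items():
                    a, b = self.eff_ptr[j], self.eff_ptr[j + 1]
                    if a == b:
                        continue
                    posts = self.syn_post[a:b]
                    slots = (step + 1 + self.syn_dstep[a:b]) % L
                    kinds = self.syn_kind[a:b]
                    amounts = self.syn_w[a:b] * np.asarray(dvals)[kinds]
                    is_inh = kinds == KIND_CODE["inhibitory"]
                    if np.any(~is_inh):
                        np.add.at(buf_E, (slots[~is_inh], posts[~is_inh]),
                                  amounts[~is_inh])
                    if np.any(is_inh):
                        np.add.at(buf_I, (slots[is_inh], posts[is_inh]),
                                  amounts[is_inh])

            if (step + 1) % stride == 0:
                record(rec_idx, (step + 1) * dt, counts_acc)
                rec_idx += 1
                counts_acc = {p: 0.0 for p, _ in pop_items}
            if (step + 1) % 2000 == 0 and not np.all(np.isfinite(st["V"])):
                raise SimulationError(
                    f"non-finite membrane potential at t = {(step + 1) * dt} ms")

        time = rec_t[:rec_idx]
        spike_times = (np.concatenate(spike_t_chunks)
                       if spike_t_chunks else np.empty(0))
        spike_neurons = (np.concatenate(spike_i_chunks)
                         if spike_i_chunks else np.empty(0, dtype=np.int64))

        rates = {}
        for p, sl in pop_items:
            mask = (spike_neurons >= sl.start) & (spike_neurons < sl.stop)
            rates[p] = population_rate(spike_times[mask], sl.stop - sl.start,
                                       kernel_width, time)

        return TrialTrace(
            config=cfg, seed=int(seed), time=time, rates=rates,
            mean_u={k: v[:rec_idx] for k, v in rec_u.items()},
            mean_x={k: v[:rec_idx] for k, v in rec_x.items()},
            mean_s={k: v[:rec_idx] for k, v in rec_s.items()},
            efficacy={k: v[:rec_idx] for k, v in rec_eff.items()},
            stimulus={k: v[:rec_idx] for k, v in rec_stim.items()},
            spike_times=spike_times, spike_neurons=spike_neurons,
            pop_slice=dict(net.pop_slice),
        )

    def assembly_efficacy(self, st_or_trace, assembly: str) -> float:
        """Current efficacy (nS) of one assembly from a raw state dict."""
        if assembly not in self.efficacy_terms:
            raise KeyError(f"unknown assembly {assembly!r}")
        terms = self.efficacy_terms[assembly]
        val = 0.0
        for code, w, pre_sl, mult in terms:
            peak = self._peak(st_or_trace, code)[pre_sl]
            val += w * float(mult @ peak)
        return val / len(terms)


def run_trial(config: NetworkConfig, seed: int, *,
              network_seed: int | None = None,
              frozen_plasticity: bool = False,
              record_stride: float = 1.0,
              kernel_width: float = 50.0) -> TrialTrace:
    """Build a network and simulate one full trial.

    ``seed`` drives the membrane noise; ``network_seed`` (default: the
    config seed) drives the connectivity draw.
    """
    validate_config(config)
    net = build_network(config, seed=network_seed)
    sim = SpikingSimulator(net)
    return sim.run(seed=seed, frozen_plasticity=frozen_plasticity,
                   record_stride=record_stride, kernel_width=kernel_width)
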