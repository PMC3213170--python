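"""Spiking simulator: membrane dynamics, plasticity, recording."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reorgnet as rn
from reorgnet.config import default_config, excitatory_neuron_defaults
from reorgnet.network import build_network
from reorgnet.spiking import (NeuronState, SpikingSimulator,
                              apply_spike_plasticity, external_conductance,
                              membrane_step, population_rate, rk4_membrane)

from .oracles import (lif_isi, lif_steady_state, simulate_reference,
                      tm_plasticity_events)


# ---------------------------------------------------------------------------
# membrane

def test_leak_equilibrium_is_fixed_point():
    """With zero synaptic conductance and no noise the membrane stays at
    the leak reversal and never spikes."""
    p = excitatory_neuron_defaults(noise_sigma=0.0)
    state = NeuronState(np.full(5, p.leak_reversal), np.zeros(5, dtype=int))
    for _ in range(1000):
        state, spikes = membrane_step(state, 0.0, 0.0, p, dt=0.1)
        assert spikes.size == 0
    np.testing.assert_allclose(state.membrane_potential, p.leak_reversal,
                               atol=1e-9)


def test_bias_only_steady_state_subthreshold():
    """Under the 8.35 nS excitatory bias alone the membrane settles at
    the conductance-weighted steady state ~ -53.7 mV, just below the
    -52 mV threshold."""
    p = excitatory_neuron_defaults(noise_sigma=0.0)
    target = lif_steady_state(p.leak_conductance, p.leak_reversal,
                              8.35, p.excitatory_reversal, 0.0,
                              p.inhibitory_reversal)
    assert target == pytest.approx((25 * -70 + 8.35 * -5) / 33.35)
    assert target < p.threshold
    state = NeuronState(np.full(3, p.leak_reversal), np.zeros(3, dtype=int))
    for _ in range(3000):   # 300 ms >> membrane time constant
        state, spikes = membrane_step(state, 8.35, 0.0, p, dt=0.1)
        assert spikes.size == 0
    np.testing.assert_allclose(state.membrane_potential, target, atol=1e-6)


@pytest.mark.parametrize("g_E", [10.0, 12.0, 15.0])
def test_suprathreshold_isi_matches_analytic_lif(g_E):
    """Constant suprathreshold drive fires periodically with the
    inter-spike interval given by the closed-form LIF charging time plus
    the refractory period (to one integration step)."""
    p = excitatory_neuron_defaults(noise_sigma=0.0)
    dt = 0.1
    state = NeuronState(np.array([p.reset]), np.zeros(1, dtype=int))
    times = []
    for k in range(40000):
        state, spikes = membrane_step(state, g_E, 0.0, p, dt=dt)
        if spikes.size:
            times.append((k + 1) * dt)
    assert len(times) >= 10
    isis = np.diff(times)
    expected = lif_isi(p, g_E)
    assert np.all(np.abs(isis - expected) <= dt + 1e-9)


def test_rk4_accuracy_against_exact_exponential():
    """One RK4 step of the linear membrane equation agrees with the
    exact exponential solution to ~(dt/tau)^5."""
    p = excitatory_neuron_defaults()
    g_E, dt = 8.0, 0.1
    a = (p.leak_conductance + g_E) / (p.membrane_capacitance * 1e3)
    v_inf = lif_steady_state(p.leak_conductance, p.leak_reversal, g_E,
                             p.excitatory_reversal, 0.0, p.inhibitory_reversal)
    v0 = -65.0
    exact = v_inf + (v0 - v_inf) * np.exp(-a * dt)
    num = rk4_membrane(v0, p.leak_conductance, p.leak_reversal, g_E,
                       p.excitatory_reversal, 0.0, p.inhibitory_reversal,
                       p.membrane_capacitance, dt)
    assert num == pytest.approx(exact, abs=1e-10)


# ---------------------------------------------------------------------------
# short-term plasticity

def test_single_spike_from_rest():
    """From rest (u = U = 0.2, x = 1) one spike gives u = 0.36, releases
    a peak of 0.36 and leaves x = 0.64."""
    u, x, peak = apply_spike_plasticity(0.2, 1.0, 0.2)
    assert u == pytest.approx(0.36)
    assert peak == pytest.approx(0.36)
    assert x == pytest.approx(0.64)


def test_depression_peaks_decrease_for_fast_trains():
    """Two spikes separated by much more than tau_u but much less than
    tau_x: utilization has recovered but resources have not, so the
    second release is smaller (net depression)."""
    events = tm_plasticity_events([0.0, 150.0], U=0.2, tau_u=20.0,
                                  tau_x=600.0)
    assert events[1][2] < events[0][2]
    # sustained 25 Hz train keeps depressing
    train = tm_plasticity_events(np.arange(0, 400, 40.0), U=0.2,
                                 tau_u=20.0, tau_x=600.0)
    peaks = [e[2] for e in train]
    assert all(b < a for a, b in zip(peaks, peaks[1:]))


def test_facilitation_peaks_grow_at_moderate_rates():
    """A 10 Hz train through a facilitating synapse (slow utilization
    decay, fast resource recovery) releases increasing peaks."""
    train = tm_plasticity_events(np.arange(0, 500, 100.0), U=0.2,
                                 tau_u=600.0, tau_x=100.0)
    peaks = [e[2] for e in train]
    assert peaks[1] > peaks[0]
    assert max(peaks) > 0.3


@settings(max_examples=200, deadline=None, derandomize=True)
@given(u=st.floats(0, 1), x=st.floats(0, 1), U=st.floats(0.01, 1))
def test_plasticity_update_stays_bounded(u, x, U):
    """The per-spike update maps [0,1]^2 into itself and releases a
    nonnegative peak no larger than the available resources."""
    u2, x2, peak = apply_spike_plasticity(u, x, U)
    assert 0.0 <= u2 <= 1.0
    assert 0.0 <= x2 <= 1.0 + 1e-12
    assert 0.0 <= peak <= x + 1e-12
    assert x2 == pytest.approx(x - peak)


# ---------------------------------------------------------------------------
# stimulus

def test_activation_ramp_and_sensory_window():
    cfg = default_config()
    proto = cfg.protocol
    on = proto.goal_display_onset
    assert external_conductance(proto, "A", on - 1.0) == 0.0
    # mid-ramp: half the 0.35 nS activation plus the 0.2 nS sensory pulse
    mid = external_conductance(proto, "A", on + proto.activation_ramp / 2)
    assert mid == pytest.approx(0.5 * 0.35 + 0.2)
    mid_c = external_conductance(proto, "C", on + proto.activation_ramp / 2)
    assert mid_c == pytest.approx(0.5 * 0.35)        # no sensory on C for G1
    late = external_conductance(proto, "A", on + 1000.0)
    assert late == pytest.approx(0.35)                # sensory over, full ramp
    assert external_conductance(proto, "IN", on + 100.0) == 0.0


# ---------------------------------------------------------------------------
# vectorized simulator vs event-driven scalar reference

def test_vectorized_matches_event_driven_reference(tiny_network):
    """Spike-for-spike equality with an independently written scalar
    event-driven reference on a noise-free 10-neuron network (exercises
    integration, thresholds, refractoriness, delays and plasticity)."""
    net = build_network(tiny_network, seed=5)
    sim = SpikingSimulator(net)
    trace = sim.run(seed=0, duration=800.0)
    ref_t, ref_i = simulate_reference(net, duration=800.0)
    assert len(ref_t) > 50, "fixture should actually fire"
    assert len(trace.spike_times) == len(ref_t)
    np.testing.assert_allclose(trace.spike_times, ref_t, atol=1e-9)
    np.testing.assert_array_equal(trace.spike_neurons, ref_i)


def test_resting_network_is_noise_free_fixed_point(fast_config):
    """Without noise and without stimulus no neuron ever crosses
    threshold over 10 seconds."""
    cfg = fast_config.copy()
    for p in cfg.populations.values():
        p.neuron.noise_sigma = 0.0
    cfg.protocol.activation_amplitude = 0.0
    cfg.protocol.sensory_amplitude = 0.0
    cfg.protocol.trial_duration = 10_000.0
    trace = rn.run_trial(cfg, seed=0, record_stride=10.0)
    assert trace.spike_times.size == 0


def test_no_stimulus_rates_near_zero(fast_config):
    """With the calibrated noise but no external input the network
    stays near rest for the whole trial."""
    cfg = fast_config.copy()
    cfg.protocol.activation_amplitude = 0.0
    cfg.protocol.sensory_amplitude = 0.0
    trace = rn.run_trial(cfg, seed=9)
    for p in rn.EXC_POPS:
        assert trace.rates[p].mean() < 1.0
        assert trace.rates[p].max() < 10.0


# ---------------------------------------------------------------------------
# recorded quantities

def test_trace_bounds_and_readout(scaled_batch):
    """Recorded plasticity means stay in [0,1], rates and efficacies are
    nonnegative, and the read-outs are the summed source-population
    rates."""
    for res in scaled_batch.trials[:4]:
        tr = res.trace
        for d in (tr.mean_u, tr.mean_x, tr.mean_s):
            for v in d.values():
                assert v.min() >= -1e-12 and v.max() <= 1.0 + 1e-12
        for v in tr.rates.values():
            assert v.min() >= 0.0
        for v in tr.efficacy.values():
            assert v.min() >= 0.0
        ro = tr.readout
        np.testing.assert_allclose(ro["A1"], tr.rates["A"] + tr.rates["D"])
        np.testing.assert_allclose(ro["A2"], tr.rates["B"] + tr.rates["C"])


def test_population_rate_properties():
    rng = np.random.default_rng(0)
    grid = np.arange(0.0, 1000.0, 1.0)
    spikes = rng.uniform(100.0, 900.0, size=400)
    r = population_rate(spikes, pop_size=20, kernel_width=50.0,
                        time_grid=grid)
    assert np.all(r >= 0)
    # count conservation: integral(rate) * pop_size ~ n_spikes
    total = np.trapezoid(r, grid) / 1000.0 * 20
    assert total == pytest.approx(400, rel=0.02)
    # halving the kernel width leaves the integral unchanged
    r2 = population_rate(spikes, pop_size=20, kernel_width=25.0,
                         time_grid=grid)
    assert np.trapezoid(r2, grid) == pytest.approx(np.trapezoid(r, grid),
                                                   rel=0.02)
    # mean rate ~ N/(n*T) over the support
    assert r[(grid > 200) & (grid < 800)].mean() == pytest.approx(
        400 / (20 * 0.8), rel=0.15)
    # empty record -> zero series
    empty = population_rate(np.empty(0), 20, 50.0, grid)
    assert np.all(empty == 0)


def test_resting_efficacy_values():
    """At rest the assembly efficacy is the summed weight times the
    resting release peak: W for constant classes, 0.2 W for plastic
    ones."""
    cfg = default_config(variant="depression_only", n_exc=30, n_inh=30)
    cfg.protocol.trial_duration = 600.0
    cfg.protocol.goal_display_onset = 550.0
    tr = rn.run_trial(cfg, seed=0)
    # action assembly is constant kind, W = 0.5 -> efficacy 0.5
    assert tr.efficacy["A&D"][0] == pytest.approx(0.5, rel=1e-9)
    # goal assembly is depressing, W = 3.0 -> resting efficacy 0.2*W
    assert tr.efficacy["A&B"][0] == pytest.approx(0.6, rel=1e-9)


def test_goal_efficacy_depresses_and_action_facilitates(scaled_batch):
    """In a default trial the displayed goal assembly's efficacy falls
    below its resting value while the action assemblies' efficacy rises,
    so the dominant (highest-efficacy) assembly switches (in most
    scaled-down trials)."""
    switched = 0
    for res in scaled_batch.trials:
        tr = res.trace
        goal_asm = "A&B" if res.goal == "G1" else "C&D"
        rest = tr.efficacy[goal_asm][0]
        late = tr.time > 2000.0
        if tr.efficacy[goal_asm][late].mean() < rest:
            act_eff = np.maximum(tr.efficacy["A&D"], tr.efficacy["B&C"])
            if np.any(act_eff[late] > tr.efficacy[goal_asm][late]):
                switched += 1
    assert switched >= len(scaled_batch.trials) * 0.7


def test_trial_reproducibility(fast_config):
    cfg = fast_config.copy()
    cfg.protocol.trial_duration = 1200.0
    a = rn.run_trial(cfg, seed=42)
    b = rn.run_trial(cfg, seed=42)
    np.testing.assert_array_equal(a.spike_times, b.spike_times)
    np.testing.assert_array_equal(a.spike_neurons, b.spike_neurons)
    c = rn.run_trial(cfg, seed=43)
    assert (len(c.spike_times) != len(a.spike_times)
            or not np.array_equal(c.spike_times, a.spike_times))
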