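"""Deterministic mean-field reduction of the spiking network.

Each excitatory population is reduced to one constant-synapse mean
activity s (the population average of the fraction of open channels),
each plastic connection class to mean utilization u and mean resources
x, and the interneuron pool to one inhibitory activity s_I.  Population
firing rates are algebraic functions of the conductances through a
Naka--Rushton transfer function fitted to uncoupled pools of the spiking
neurons:

    r(g_E, g_I) = r_max [g - theta]_+^M / (h^M + [g - theta]_+^M),
    g = g_E - c_I g_I,  M = 2

with rates in kHz and conductances in nS.  The state dynamics are

    ds/dt   = (s_inf(r) - s) / tau_s,
    s_inf(r) = rho (1 - exp(-1/rho)),     rho = r tau_s
    du/dt   = (U - u) / tau_u + U (1 - u) r
    dx/dt   = (1 - x) / tau_x - u+ x r,   u+ = u + U (1 - u)

and a plastic class contributes activity s * u * x (the constant-kind
mean scaled by the release peak), so at rest it is U times as strong as
a constant synapse of the same summed weight, exactly as in the spiking
model.

The goal-assembly weight of the ``all_types`` wiring is reduced to
1.9 nS here (see :func:`reorgnet.config.meanfield_config`): without
spiking fluctuations the deterministic model needs the weaker coupling
to leave the goal state in a comparable time.  Perfectly symmetric
wirings sit on a saddle forever, so trials apply a small
symmetry-breaking pulse (0.01 nS, 200 ms) to one action assembly at
goal-display onset.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources as _resources

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .config import (EXC_POPS, INH_POP, NetworkConfig, StimulusProtocol,
                     meanfield_config, validate_config)
from .spiking import external_conductance, rk4_membrane

N_FAST = 5          # s_A..s_D, s_I
STATE_DIM = 21      # fast + (u_F, x_F, u_D, x_D) per excitatory population


class FitError(RuntimeError):
    """Rate-function fit failure; carries residual diagnostics."""


# ---------------------------------------------------------------------------
# transfer function

@dataclass
class NakaRushton:
    """Saturating intensity-response curve of one neuron class."""

    r_max: float   # kHz
    theta: float   # nS, drive threshold
    h: float       # nS, half-saturation drive above threshold
    c_inh: float   # weight of inhibitory conductance in the effective drive
    M: float = 2.0

    def rate(self, g_E, g_I=0.0):
        """Firing rate in kHz for total conductances in nS."""
        g = np.maximum(np.asarray(g_E, dtype=float) - self.c_inh * g_I
                       - self.theta, 0.0)
        gM = g ** self.M
        return self.r_max * gM / (self.h ** self.M + gM)


@dataclass
class RateFunctionParams:
    """Fitted transfer functions and their fit diagnostics."""

    excitatory: NakaRushton
    inhibitory: NakaRushton
    residual_rms: dict = field(default_factory=dict)   # class -> kHz

    def to_json(self) -> str:
        return json.dumps({
            "excitatory": asdict(self.excitatory),
            "inhibitory": asdict(self.inhibitory),
            "residual_rms": self.residual_rms,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RateFunctionParams":
        d = json.loads(text)
        return cls(excitatory=NakaRushton(**d["excitatory"]),
                   inhibitory=NakaRushton(**d["inhibitory"]),
                   residual_rms=d.get("residual_rms", {}))


_DEFAULT_RATE_PARAMS = None


def default_rate_params() -> RateFunctionParams:
    """Packaged transfer-function fit for the default neuron parameters.

    Produced by :func:`fit_rate_function` on surfaces sampled from
    uncoupled pools of the default excitatory and inhibitory neurons
    (see ``reorgnet/data/rate_params.json`` for the fit residuals).
    """
    global _DEFAULT_RATE_PARAMS
    if _DEFAULT_RATE_PARAMS is None:
        text = (_resources.files("reorgnet") / "data" / "rate_params.json").read_text()
        _DEFAULT_RATE_PARAMS = RateFunctionParams.from_json(text)
    return _DEFAULT_RATE_PARAMS


# ---------------------------------------------------------------------------
# sampling the rate surface of an uncoupled pool

def sample_rate_surface(neuron_params, g_E_grid, g_I_grid, *,
                        duration: float = 1000.0, n_neurons: int = 100,
                        seed: int = 0, dt: float = 0.1,
                        discard: float = 200.0):
    """Mean firing rate of an uncoupled pool under clamped conductances.

    Simulates ``n_neurons`` independent neurons at every (g_E, g_I) grid
    point for ``duration`` ms (the first ``discard`` ms are excluded from
    the rate estimate) and returns an array of shape
    ``(len(g_E_grid), len(g_I_grid))`` with rates in kHz.  ``g_E_grid``
    is the *total* excitatory conductance (bias included).
    """
    g_E_grid = np.asarray(g_E_grid, dtype=float)
    g_I_grid = np.asarray(g_I_grid, dtype=float)
    gE, gI = np.meshgrid(g_E_grid, g_I_grid, indexing="ij")
    shape = gE.shape
    gE = np.repeat(gE.ravel(), n_neurons)
    gI = np.repeat(gI.ravel(), n_neurons)
    n = gE.size

    p = neuron_params
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA7E]))
    V = np.full(n, p.leak_reversal)
    ref = np.zeros(n, dtype=np.int64)
    ref_steps = int(round(p.refractory / dt))
    n_steps = int(round(duration / dt))
    discard_step = int(round(discard / dt))
    counts = np.zeros(n)
    sq_dt = np.sqrt(dt)

    for step in range(n_steps):
        active = ref == 0
        V_new = rk4_membrane(V, p.leak_conductance, p.leak_reversal,
                             gE, p.excitatory_reversal,
                             gI, p.inhibitory_reversal,
                             p.membrane_capacitance, dt)
        V_new = np.where(active, V_new, p.reset)
        if p.noise_sigma > 0:
            V_new = np.where(
                active, V_new + p.noise_sigma * sq_dt * rng.standard_normal(n),
                V_new)
        spiking = active & (V_new >= p.threshold)
        V_new[spiking] = p.reset
        ref = np.maximum(ref - 1, 0)
        ref[spiking] = ref_steps
        V = V_new
        if step >= discard_step:
            counts += spiking

    window = (n_steps - discard_step) * dt  # ms
    rates = counts.reshape(-1, n_neurons).mean(axis=1) / window  # kHz
    return rates.reshape(shape)


def fit_rate_function(g_E_grid, g_I_grid, rates, *, M: float = 2.0,
                      label: str = "excitatory",
                      rate_floor: float = 0.005) -> NakaRushton:
    """Least-squares Naka--Rushton fit to a sampled rate surface.

    Residuals are weighted by ``1 / (rate + rate_floor)`` (rates in
    kHz), i.e. an approximate relative error.  Near the firing onset the
    observed rates are orders of magnitude below saturation, and the
    onset region is what decides the fixed-point structure of the
    reduced network, so it must not be swamped by the saturated part of
    the surface.

    Returns the fitted :class:`NakaRushton`; raises :class:`FitError`
    with residual diagnostics if the optimizer fails.
    """
    g_E_grid = np.asarray(g_E_grid, dtype=float)
    g_I_grid = np.asarray(g_I_grid, dtype=float)
    rates = np.asarray(rates, dtype=float)
    gE, gI = np.meshgrid(g_E_grid, g_I_grid, indexing="ij")
    weight = 1.0 / (rates + rate_floor)

    def resid(params):
        r_max, theta, h, c_inh = params
        nr = NakaRushton(r_max=r_max, theta=theta, h=h, c_inh=c_inh, M=M)
        return ((nr.rate(gE, gI) - rates) * weight).ravel()

    r0 = max(rates.max(), 1e-3)
    x0 = np.array([2.0 * r0, float(np.median(g_E_grid)), 5.0, 2.0])
    try:
        sol = least_squares(resid, x0, bounds=([1e-4, 0.0, 1e-3, 0.0],
                                               [10.0, 50.0, 100.0, 50.0]))
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise FitError(f"{label}: optimizer failed: {exc}") from exc
    if not sol.success:
        raise FitError(f"{label}: no convergence, residual RMS "
                       f"{np.sqrt(np.mean(sol.fun ** 2)):.4g} kHz")
    r_max, theta, h, c_inh = sol.x
    return NakaRushton(r_max=float(r_max), theta=float(theta), h=float(h),
                       c_inh=float(c_inh), M=M)


def fit_default_rate_params(config: NetworkConfig | None = None, *,
                            seed: int = 0, n_neurons: int = 200,
                            duration: float = 2000.0) -> RateFunctionParams:
    """Full fitting pipeline for a configuration's neuron classes."""
    from .config import default_config
    cfg = config or default_config()
    # grids denser around the firing thresholds of the two classes so the
    # fitted curve reproduces the onset of firing, which sets the
    # attractor structure of the reduced model
    grids = {
        "excitatory": np.array([0.0, 2.0, 4.0, 6.0, 7.0, 8.0, 8.5, 9.0, 9.5,
                                10.0, 10.5, 11.0, 12.0, 13.0, 14.0, 16.0,
                                18.0, 20.0]),
        "inhibitory": np.array([0.0, 2.0, 3.0, 4.0, 4.5, 5.0, 5.5, 6.0, 6.5,
                                7.0, 8.0, 9.0, 10.0, 12.0, 14.0]),
    }
    gI = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0])
    out = {}
    rms = {}
    for label, pop in (("excitatory", cfg.populations["A"]),
                       ("inhibitory", cfg.populations[INH_POP])):
        gE = grids[label]
        surf = sample_rate_surface(pop.neuron, gE, gI, seed=seed,
                                   n_neurons=n_neurons, duration=duration)
        nr = fit_rate_function(gE, gI, surf, label=label)
        out[label] = nr
        rms[label] = float(np.sqrt(np.mean((nr.rate(*np.meshgrid(gE, gI,
                           indexing="ij")) - surf) ** 2)))
    return RateFunctionParams(excitatory=out["excitatory"],
                              inhibitory=out["inhibitory"], residual_rms=rms)


# ---------------------------------------------------------------------------
# the mean-field model

def stationary_activity(r, tau_s):
    """Stationary mean synaptic activity at firing rate ``r`` (kHz).

    Time average of a synapse whose activity is set to 1 by each
    presynaptic spike and decays with ``tau_s``, for a *regular* spike
    train of rate r (driven integrate-and-fire neurons fire
    quasi-regularly):  with rho = r tau_s,

        s_inf = rho (1 - exp(-1/rho)),

    which is r tau_s at low rates and saturates at 1.
    """
    rho = np.asarray(r, dtype=float) * tau_s
    safe = np.maximum(rho, 1e-12)
    return np.where(rho > 0, np.minimum(safe * (1.0 - np.exp(-1.0 / safe)), 1.0),
                    0.0)


class MeanFieldModel:
    """Population-rate model over the 21-dimensional mean-field state.

    State layout: ``[s_A, s_B, s_C, s_D, s_I,
    u_F(A..D), x_F(A..D), u_D(A..D), x_D(A..D)]``.
    """

    def __init__(self, config: NetworkConfig,
                 rate_params: RateFunctionParams | None = None,
                 adjust_weights: bool = True):
        validate_config(config)
        self.config = meanfield_config(config) if adjust_weights else config
        self.params = rate_params or default_rate_params()
        cfg = self.config
        self.plas = cfg.plasticity
        self.tau_s_exc = cfg.tau_s_exc
        self.tau_s_inh = cfg.tau_s_inh
        self.bias = np.array(
            [cfg.populations[p].bias_conductance for p in EXC_POPS]
            + [cfg.populations[INH_POP].bias_conductance])
        # weight matrices per synapse kind: W[k, l] = summed weight l -> k
        # over the 5 nodes (A..D, IN)
        pops = list(EXC_POPS) + [INH_POP]
        self.pop_index = {p: i for i, p in enumerate(pops)}
        self.W = {k: np.zeros((5, 5))
                  for k in ("facilitation", "depression", "constant",
                            "inhibitory")}
        for conn in cfg.connections:
            k_post = self.pop_index[conn.post_pop]
            k_pre = self.pop_index[conn.pre_pop]
            self.W[conn.kind][k_post, k_pre] += conn.summed_weight

    # -- state helpers ------------------------------------------------------
    def resting_state(self) -> np.ndarray:
        UF = self.plas["facilitation"].U_rest
        UD = self.plas["depression"].U_rest
        y = np.zeros(STATE_DIM)
        y[5:9] = UF
        y[9:13] = 1.0
        y[13:17] = UD
        y[17:21] = 1.0
        return y

    @staticmethod
    def split(y):
        return (y[..., 0:4], y[..., 4], y[..., 5:9], y[..., 9:13],
                y[..., 13:17], y[..., 17:21])

    # -- pieces -------------------------------------------------------------
    def plastic_activity(self, s_exc, u, x):
        """Mean activity of a plastic class: constant-kind mean scaled by
        the release peak u*x."""
        return s_exc * u * x

    def conductances(self, y, g_ext):
        """Total (g_E, g_I) per node given state and external input (5,)."""
        s_exc, s_I, uF, xF, uD, xD = self.split(y)
        act = {
            "constant": np.concatenate([s_exc, [0.0]]),
            "facilitation": np.concatenate([self.plastic_activity(s_exc, uF, xF), [0.0]]),
            "depression": np.concatenate([self.plastic_activity(s_exc, uD, xD), [0.0]]),
            "inhibitory": np.concatenate([np.zeros(4), [s_I]]),
        }
        g_E = self.bias + g_ext
        for kind in ("constant", "facilitation", "depression"):
            g_E = g_E + self.W[kind] @ act[kind]
        g_I = self.W["inhibitory"] @ act["inhibitory"]
        return g_E, g_I

    def rates(self, y, g_ext=None):
        """Node firing rates (kHz): A..D from the excitatory transfer
        function, IN from the inhibitory one."""
        if g_ext is None:
            g_ext = np.zeros(5)
        g_E, g_I = self.conductances(y, g_ext)
        r = np.empty(5)
        r[:4] = self.params.excitatory.rate(g_E[:4], g_I[:4])
        r[4] = self.params.inhibitory.rate(g_E[4], g_I[4])
        return r

    def external(self, protocol: StimulusProtocol, t: float) -> np.ndarray:
        return np.array([external_conductance(protocol, p, t)
                         for p in EXC_POPS] + [0.0])

    # -- dynamics -----------------------------------------------------------
    def rhs(self, y, g_ext=None):
        """Time derivative of the full state (algebraic rates)."""
        if g_ext is None:
            g_ext = np.zeros(5)
        s_exc, s_I, uF, xF, uD, xD = self.split(y)
        r = self.rates(y, g_ext)
        r_exc, r_in = r[:4], r[4]
        dy = np.empty(STATE_DIM)
        dy[0:4] = (stationary_activity(r_exc, self.tau_s_exc) - s_exc) / self.tau_s_exc
        dy[4] = (stationary_activity(r_in, self.tau_s_inh) - s_I) / self.tau_s_inh
        pF = self.plas["facilitation"]
        pD = self.plas["depression"]
        for sl_u, sl_x, pp in (((5, 9), (9, 13), pF), ((13, 17), (17, 21), pD)):
            u = y[sl_u[0]:sl_u[1]]
            x = y[sl_x[0]:sl_x[1]]
            u_plus = u + pp.U_rest * (1.0 - u)
            dy[sl_u[0]:sl_u[1]] = (pp.U_rest - u) / pp.tau_u \
                + pp.U_rest * (1.0 - u) * r_exc
            dy[sl_x[0]:sl_x[1]] = (1.0 - x) / pp.tau_x - u_plus * x * r_exc
        return dy

    def rhs_t(self, t, y, protocol):
        return self.rhs(y, self.external(protocol, t))


@dataclass
class MeanFieldTrajectory:
    """Dense mean-field solution with the same surface as a TrialTrace."""

    config: NetworkConfig
    model: MeanFieldModel
    time: np.ndarray
    states: np.ndarray                  # (T, 21)
    rates: dict = field(default_factory=dict)   # pop -> Hz

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.clip(np.searchsorted(self.time, t), 0, len(self.time) - 1))
        return self.states[i]

    def to_frame(self):
        import pandas as pd
        cols = {"time_ms": self.time}
        for p in self.rates:
            cols[f"rate_{p}_hz"] = self.rates[p]
        names = ([f"s_{p}" for p in EXC_POPS] + ["s_IN"]
                 + [f"uF_{p}" for p in EXC_POPS] + [f"xF_{p}" for p in EXC_POPS]
                 + [f"uD_{p}" for p in EXC_POPS] + [f"xD_{p}" for p in EXC_POPS])
        for j, name in enumerate(names):
            cols[name] = self.states[:, j]
        return pd.DataFrame(cols)


def simulate_mean_field(config: NetworkConfig,
                        protocol: StimulusProtocol | None = None, *,
                        rate_params: RateFunctionParams | None = None,
                        adjust_weights: bool = True,
                        symmetry_break: str | None = "A1",
                        record_stride: float = 1.0,
                        rtol: float = 1e-8,
                        atol: float = 1e-10) -> MeanFieldTrajectory:
    """Integrate the mean-field model over one trial protocol.

    When the protocol carries no perturbation and ``symmetry_break``
    names an action assembly, the canonical 0.01 nS x 200 ms
    symmetry-breaking pulse is applied to it at goal-display onset
    (otherwise a perfectly symmetric network never leaves the saddle).
    """
    model = MeanFieldModel(config, rate_params=rate_params,
                           adjust_weights=adjust_weights)
    protocol = (protocol or config.protocol)
    if protocol.perturbation_amplitude == 0 and symmetry_break is not None:
        import copy as _copy
        protocol = _copy.deepcopy(protocol)
        protocol.perturbation_amplitude = 0.01
        protocol.perturbation_onset = 0.0
        protocol.perturbation_width = 200.0
        protocol.perturbation_target = symmetry_break
    T = protocol.trial_duration
    t_eval = np.arange(0.0, T + record_stride / 2, record_stride)
    sol = solve_ivp(model.rhs_t, (0.0, T), model.resting_state(),
                    t_eval=t_eval, args=(protocol,), method="RK45",
                    rtol=rtol, atol=atol, max_step=25.0)
    if not sol.success:
        raise RuntimeError(f"mean-field integration failed: {sol.message}")
    states = sol.y.T
    rates_k = np.array([MeanFieldModel.rates(model, y,
                                             model.external(protocol, t))
                        for t, y in zip(sol.t, states)])
    rates = {p: rates_k[:, i] * 1000.0 for i, p in enumerate(EXC_POPS)}
    rates[INH_POP] = rates_k[:, 4] * 1000.0
    traj = MeanFieldTrajectory(config=model.config, model=model,
                               time=sol.t, states=states, rates=rates)
    traj.protocol = protocol
    return traj
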