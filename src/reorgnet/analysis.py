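"""Derived measures: state-space reduction, selectivity, transition times.

The network's population activity lives, after averaging, in a
4-dimensional rate space (populations A--D).  Two orthogonal contrasts
span the task-relevant plane: the *goal axis* (A+B) - (C+D) and the
*action axis* (A+D) - (B+C).  A principal-component basis fitted to
rest-centered trial rates recovers these axes empirically; transition
times are read off as the moment the action-axis projection overtakes
the goal-axis projection and stays dominant.

Selectivity is measured as in delayed-response electrophysiology: at
each time step the rate of a unit is regressed, across trials, on
dummy regressors coding whether the trial's goal (action) was the
unit's preferred one, and the two coefficient time courses are
normalized to a common unit peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .config import EXC_POPS, NetworkConfig, validate_config
from .network import build_network
from .spiking import SpikingSimulator, TrialTrace, _first_sustained

#: architectural preferences: population -> (preferred goal, preferred action)
UNIT_PREFERENCES = {
    "A": ("G1", "A1"),
    "B": ("G1", "A2"),
    "C": ("G2", "A2"),
    "D": ("G2", "A1"),
}

GOAL_CONTRAST = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
ACTION_CONTRAST = np.array([1.0, -1.0, -1.0, 1.0]) / 2.0


# ---------------------------------------------------------------------------
# principal components

@dataclass
class PCBasis:
    """Rest-centered principal-component basis over the four excitatory
    populations, with the components labeled as goal / action axes by
    their alignment with the architectural contrasts."""

    components: np.ndarray       # (n_components, 4) orthonormal loadings
    rest_offset: np.ndarray      # (4,) resting rates subtracted before projection
    explained_variance_ratio: np.ndarray
    goal_axis: int = 0
    action_axis: int = 1

    def project(self, rates) -> np.ndarray:
        """Project rate vectors (..., 4) onto the PC axes."""
        return (np.asarray(rates) - self.rest_offset) @ self.components.T

    def project_trace(self, trace: TrialTrace) -> np.ndarray:
        return self.project(_rate_matrix(trace))


def _rate_matrix(trace) -> np.ndarray:
    """(T, 4) rates of the excitatory populations."""
    if isinstance(trace, TrialTrace):
        return np.column_stack([trace.rates[p] for p in EXC_POPS])
    rates = trace.rates  # mean-field style object with a rates dict
    return np.column_stack([rates[p] for p in EXC_POPS])


def _rest_window_mean(trace, rest_end: float | None) -> np.ndarray:
    t = trace.time
    if rest_end is None:
        cfg = getattr(trace, "config", None)
        rest_end = cfg.protocol.goal_display_onset if cfg is not None else t[0]
    mask = t < rest_end
    R = _rate_matrix(trace)
    if not np.any(mask):
        return np.zeros(R.shape[1])
    return R[mask].mean(axis=0)


def fit_pca(traces, n_components: int = 4, rest_end: float | None = None) -> PCBasis:
    """Fit the rest-centered PC basis on pooled trial rates.

    ``traces`` is a sequence of :class:`TrialTrace` (or mean-field
    trajectories exposing ``time`` and ``rates``).  The resting offset is
    the mean rate before ``rest_end`` (default: the goal-display onset of
    each trace's protocol), so the resting state projects to the origin.
    """
    traces = list(traces)
    if len(traces) < 2:
        raise ValueError("need at least 2 trajectories to fit a PC basis")
    rest = np.mean([_rest_window_mean(tr, rest_end) for tr in traces], axis=0)
    X = np.vstack([_rate_matrix(tr) - rest for tr in traces])
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer pooled samples than dimensions")
    n_components = min(n_components, X.shape[1])
    pca = PCA(n_components=n_components)
    pca.fit(X)
    comps = pca.components_.copy()
    # deterministic sign: largest-|loading| entry positive
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    basis = PCBasis(components=comps, rest_offset=rest,
                    explained_variance_ratio=pca.explained_variance_ratio_.copy())
    _label_axes(basis)
    return basis


def _label_axes(basis: PCBasis) -> None:
    """Assign goal/action axis labels by contrast alignment (greedy)."""
    scores = np.abs(basis.components @ np.column_stack([GOAL_CONTRAST,
                                                        ACTION_CONTRAST]))
    # greedy assignment over (component, contrast) pairs
    taken_comp, labels = set(), {}
    order = np.dstack(np.unravel_index(np.argsort(-scores, axis=None),
                                       scores.shape))[0]
    for comp, which in order:
        if comp in taken_comp or which in labels:
            continue
        labels[which] = int(comp)
        taken_comp.add(int(comp))
        if len(labels) == 2:
            break
    basis.goal_axis = labels.get(0, 0)
    basis.action_axis = labels.get(1, 1 if basis.goal_axis != 1 else 0)
    # orient: goal-1 (A&B) positive on the goal axis, action-1 (A&D)
    # positive on the action axis
    if basis.components[basis.goal_axis] @ GOAL_CONTRAST < 0:
        basis.components[basis.goal_axis] *= -1
    if basis.components[basis.action_axis] @ ACTION_CONTRAST < 0:
        basis.components[basis.action_axis] *= -1


# ---------------------------------------------------------------------------
# selectivity regression

@dataclass
class SelectivityTimecourse:
    """Normalized goal / action selectivity over time for one unit.

    ``goal`` and ``action`` are the dummy-regression coefficients divided
    by the single maximum absolute coefficient across both series, so the
    global peak magnitude is 1.
    """

    time: np.ndarray
    goal: np.ndarray
    action: np.ndarray
    intercept: np.ndarray
    raw_goal: np.ndarray
    raw_action: np.ndarray
    unit: str = "mean"
    goal_onset: float | None = None


def selectivity_timecourse(traces, goals, actions, unit: str = "mean",
                           normalize: bool = True) -> SelectivityTimecourse:
    """Dummy-variable regression of firing rate on goal and action.

    At every time step the rates of ``unit`` across trials are regressed
    on an intercept, a goal dummy (1 when the trial's goal is the unit's
    preferred goal) and an action dummy (1 for the preferred action):

        F = a0 + a_G * Goal + a_A * Action

    by ordinary least squares over trials.  ``unit`` is one of
    ``A/B/C/D`` or ``"mean"``, which averages the coefficient time
    courses of the four populations (each coded with its own
    preferences).  Trials whose action is None are rejected.

    Raises ``ValueError`` naming a missing (goal, action) pattern when
    the design is rank deficient.
    """
    traces = list(traces)
    goals = list(goals)
    actions = list(actions)
    if any(a is None for a in actions):
        raise ValueError("every trial needs a selected action")
    patterns = {(g, a) for g in ("G1", "G2") for a in ("A1", "A2")}
    seen = set(zip(goals, actions))
    missing = patterns - seen
    if missing:
        raise ValueError(f"missing (goal, action) pattern(s): {sorted(missing)}")

    time = traces[0].time
    units = list(EXC_POPS) if unit == "mean" else [unit]
    coef_g, coef_a, coef_0 = [], [], []
    for u in units:
        pref_g, pref_a = UNIT_PREFERENCES[u]
        X = np.column_stack([
            np.ones(len(traces)),
            [1.0 if g == pref_g else 0.0 for g in goals],
            [1.0 if a == pref_a else 0.0 for a in actions],
        ])
        Y = np.stack([tr.rates[u] for tr in traces])       # (trials, T)
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)        # (3, T)
        coef_0.append(beta[0])
        coef_g.append(beta[1])
        coef_a.append(beta[2])
    raw_g = np.mean(coef_g, axis=0)
    raw_a = np.mean(coef_a, axis=0)
    intercept = np.mean(coef_0, axis=0)
    scale = max(np.max(np.abs(raw_g)), np.max(np.abs(raw_a)))
    if not normalize or scale == 0:
        scale = 1.0
    cfg = getattr(traces[0], "config", None)
    onset = cfg.protocol.goal_display_onset if cfg is not None else None
    return SelectivityTimecourse(
        time=time, goal=raw_g / scale, action=raw_a / scale,
        intercept=intercept, raw_goal=raw_g, raw_action=raw_a, unit=unit,
        goal_onset=onset)


# ---------------------------------------------------------------------------
# transition detection

def detect_transition_time(obj, basis: PCBasis | None = None,
                           hold_ms: float = 200.0,
                           search_from: float | None = None,
                           floor_frac: float = 0.2):
    """Time (ms) of the representational switch, or None when absent.

    Batch form: ``obj`` is a :class:`SelectivityTimecourse`; the switch is
    the first time the normalized action selectivity exceeds the goal
    selectivity and stays higher for ``hold_ms``.  Single-trial form:
    ``obj`` is a trace and ``basis`` a fitted :class:`PCBasis`; the
    switch is the first time |action-axis projection| exceeds |goal-axis
    projection| sustained for ``hold_ms``.

    In both forms the action measure must also exceed ``floor_frac``
    of its trial maximum, so that the near-zero epoch before the goal
    state ignites (where both measures are noise around zero) cannot
    register as a switch.
    """
    if isinstance(obj, SelectivityTimecourse):
        time = obj.time
        floor = floor_frac * np.max(np.abs(obj.action))
        dominant = (obj.action > obj.goal) & (np.abs(obj.action) > floor)
    else:
        if basis is None:
            raise ValueError("single-trial detection needs a PCBasis")
        time = obj.time
        proj = basis.project_trace(obj)
        act = np.abs(proj[:, basis.action_axis])
        floor = floor_frac * act.max()
        dominant = (act > np.abs(proj[:, basis.goal_axis])) & (act > floor)
    if search_from is None:
        if isinstance(obj, SelectivityTimecourse) and obj.goal_onset is not None:
            search_from = obj.goal_onset
        else:
            cfg = getattr(obj, "config", None)
            search_from = (cfg.protocol.goal_display_onset
                           if cfg is not None else time[0])
    dominant = dominant & (time >= search_from)
    dt = float(time[1] - time[0])
    need = max(1, int(round(hold_ms / dt)))
    idx = _first_sustained(dominant, need)
    return None if idx is None else float(time[idx])


def goal_entry_time(trace, basis: PCBasis, frac: float = 0.5,
                    hold_ms: float = 100.0):
    """First time the goal-axis projection is dominant and above
    ``frac`` of its trial maximum, sustained ``hold_ms``; None if the
    goal state is never entered."""
    proj = basis.project_trace(trace)
    g = np.abs(proj[:, basis.goal_axis])
    a = np.abs(proj[:, basis.action_axis])
    peak = g.max()
    if peak <= 0:
        return None
    mask = (g >= frac * peak) & (g > a)
    dt = float(trace.time[1] - trace.time[0])
    need = max(1, int(round(hold_ms / dt)))
    idx = _first_sustained(mask, need)
    return None if idx is None else float(trace.time[idx])


def dwell_time(trace, basis: PCBasis, hold_ms: float = 200.0):
    """Interval (ms) spent in the goal state before the switch.

    Entry is the goal-axis dominance onset; exit is the PC transition
    time.  None when either event is absent.
    """
    entry = goal_entry_time(trace, basis)
    if entry is None:
        return None
    trans = detect_transition_time(trace, basis, hold_ms=hold_ms,
                                   search_from=entry)
    if trans is None:
        return None
    return trans - entry


# ---------------------------------------------------------------------------
# batches

@dataclass
class TrialResult:
    goal: str
    action: str | None
    transition_ms: float | None
    dwell_ms: float | None
    noise_seed: int
    network_seed: int
    trace: TrialTrace


@dataclass
class BatchResult:
    """Trials, their labels and transition statistics for one batch."""

    config: NetworkConfig
    master_seed: int
    trials: list = field(default_factory=list)
    basis: PCBasis | None = None

    @property
    def pattern_counts(self) -> dict:
        counts = {}
        for tr in self.trials:
            key = (tr.goal, tr.action)
            counts[key] = counts.get(key, 0) + 1
        return counts

    @property
    def transition_times(self) -> np.ndarray:
        return np.array([t.transition_ms for t in self.trials
                         if t.transition_ms is not None])

    @property
    def dwell_times(self) -> np.ndarray:
        return np.array([t.dwell_ms for t in self.trials
                         if t.dwell_ms is not None])

    def transition_stats(self) -> dict:
        tt = self.transition_times
        return {
            "n_transitions": int(tt.size),
            "n_trials": len(self.trials),
            "mean_ms": float(tt.mean()) if tt.size else None,
            "median_ms": float(np.median(tt)) if tt.size else None,
            "sd_ms": float(tt.std(ddof=1)) if tt.size > 1 else None,
        }

    def summary_frame(self):
        import pandas as pd
        return pd.DataFrame([
            {"trial": i, "goal": t.goal, "action": t.action,
             "transition_ms": t.transition_ms, "dwell_ms": t.dwell_ms,
             "noise_seed": t.noise_seed, "network_seed": t.network_seed}
            for i, t in enumerate(self.trials)
        ])


def derive_seed(master_seed: int, index: int) -> int:
    """Counter-based per-trial seed below 2**31."""
    return int(np.random.SeedSequence([int(master_seed), int(index)])
               .generate_state(1)[0] % (2 ** 31))


def run_batch(config: NetworkConfig, n_trials: int, seed: int, *,
              goals=None, vary_network: bool = False,
              frozen_plasticity: bool = False,
              record_stride: float = 1.0) -> BatchResult:
    """Run a batch of trials with seeds derived from ``seed``.

    ``goals`` defaults to strict alternation G1/G2 (balanced).  With
    ``vary_network`` each trial also redraws the random connectivity
    (seeded); otherwise all trials share the configured network, as in a
    repeated-trials experiment on one circuit.
    """
    validate_config(config)
    if goals is None:
        goals = ["G1" if i % 2 == 0 else "G2" for i in range(n_trials)]
    if len(goals) != n_trials:
        raise ValueError("goals must have n_trials entries")

    shared_net = None if vary_network else build_network(config)
    shared_sim = None if vary_network else SpikingSimulator(shared_net)
    results = []
    for i in range(n_trials):
        cfg_i = config
        if goals[i] != config.protocol.sensory_target:
            cfg_i = config.copy()
            cfg_i.protocol.sensory_target = goals[i]
        noise_seed = derive_seed(seed, 2 * i)
        if vary_network:
            net_seed = derive_seed(seed, 2 * i + 1)
            sim = SpikingSimulator(build_network(cfg_i, seed=net_seed))
        else:
            net_seed = shared_net.seed
            sim = shared_sim
        trace = sim.run(seed=noise_seed, protocol=cfg_i.protocol,
                        frozen_plasticity=frozen_plasticity,
                        record_stride=record_stride)
        results.append(TrialResult(
            goal=goals[i], action=trace.selected_action(),
            transition_ms=None, dwell_ms=None,
            noise_seed=noise_seed, network_seed=net_seed, trace=trace))

    batch = BatchResult(config=config, master_seed=int(seed), trials=results)
    try:
        batch.basis = fit_pca([r.trace for r in results])
    except ValueError:
        batch.basis = None
    if batch.basis is not None:
        for r in results:
            r.transition_ms = detect_transition_time(r.trace, batch.basis)
            r.dwell_ms = dwell_time(r.trace, batch.basis)
    return batch
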