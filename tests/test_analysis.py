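"""PCA reduction, selectivity regression, transition detection, batches."""

from dataclasses import dataclass, field

import numpy as np
import pytest

import reorgnet as rn
from reorgnet import analysis as an
from reorgnet.config import default_config


@dataclass
class FakeTrace:
    """Minimal trace stand-in (synthetic) with a rates dict on a grid."""

    time: np.ndarray
    rates: dict = field(default_factory=dict)


def make_trace(time, rates_by_pop):
    return FakeTrace(time=np.asarray(time, dtype=float),
                     rates={p: np.asarray(v, dtype=float)
                            for p, v in rates_by_pop.items()})


# ---------------------------------------------------------------------------
# PCA

def test_pca_recovers_single_variance_direction():
    """Two trajectories that differ only along the goal contrast give a
    leading component equal to that contrast (up to sign convention)."""
    t = np.arange(0, 100.0)
    base = 10.0 * np.ones_like(t)
    bump = 5.0 * np.sin(t / 30.0)
    tr1 = make_trace(t, {p: base + s * bump for p, s in
                         zip("ABCD", (1, 1, -1, -1))})
    tr2 = make_trace(t, {p: base - s * bump for p, s in
                         zip("ABCD", (1, 1, -1, -1))})
    basis = an.fit_pca([tr1, tr2], rest_end=0.0)
    lead = basis.components[0]
    np.testing.assert_allclose(np.abs(lead), 0.5, atol=1e-8)
    assert np.sign(lead[0]) == np.sign(lead[1]) != np.sign(lead[2])
    assert basis.goal_axis == 0


def test_pca_centering_sends_rest_to_origin(scaled_batch):
    basis = scaled_batch.basis
    proj = basis.project(basis.rest_offset)
    np.testing.assert_allclose(proj, 0.0, atol=1e-10)
    # pre-onset samples project near the origin
    tr = scaled_batch.trials[0].trace
    pre = tr.time < tr.config.protocol.goal_display_onset
    pc = basis.project_trace(tr)[pre]
    assert np.abs(pc).max() < 10.0


def test_pca_requires_enough_samples():
    t = np.arange(0, 2.0)
    tr = make_trace(t, {p: np.zeros(2) for p in "ABCD"})
    with pytest.raises(ValueError):
        an.fit_pca([tr])


def test_goal_ignites_first_and_actions_separate_late(scaled_batch):
    """The displayed goal's assembly is the first to ignite in most
    trials, and by the end of the delay the selected actions separate
    cleanly along the labeled action axis."""
    b = scaled_batch
    basis = b.basis
    correct_ignition = 0
    ignitions = 0
    late_a = {}
    for res in b.trials:
        tr = res.trace
        t = tr.time
        own = rn.GOAL_ASSEMBLIES[res.goal]
        other = rn.GOAL_ASSEMBLIES["G2" if res.goal == "G1" else "G1"]
        own_rate = np.mean([tr.rates[p] for p in own], axis=0)
        other_rate = np.mean([tr.rates[p] for p in other], axis=0)
        lit = np.flatnonzero(own_rate > 10.0)
        if lit.size:
            ignitions += 1
            win = slice(lit[0], min(lit[0] + 150, len(t)))
            if own_rate[win].mean() > other_rate[win].mean():
                correct_ignition += 1
        pc = basis.project_trace(tr)
        late_a.setdefault(res.action, []).append(
            pc[t > 3000, basis.action_axis].mean())
    assert ignitions >= len(b.trials) * 0.8
    assert correct_ignition >= ignitions * 0.7
    assert np.mean(late_a["A1"]) > np.mean(late_a["A2"]) + 20


# ---------------------------------------------------------------------------
# selectivity

def _pattern_trials(rate_rule, n_per=2):
    """Fabricated trials for every (goal, action) pattern."""
    t = np.arange(0.0, 200.0)
    traces, goals, actions = [], [], []
    for g in ("G1", "G2"):
        for a in ("A1", "A2"):
            for _ in range(n_per):
                rates = {p: rate_rule(p, g, a) * np.ones_like(t)
                         for p in "ABCD"}
                traces.append(make_trace(t, rates))
                goals.append(g)
                actions.append(a)
    return traces, goals, actions


def test_pure_goal_coding_yields_goal_selectivity_one():
    """Rates depending only on whether the goal is preferred give a
    normalized goal selectivity of 1 and action selectivity of 0."""
    def rule(p, g, a):
        return 10.0 if an.UNIT_PREFERENCES[p][0] == g else 2.0

    traces, goals, actions = _pattern_trials(rule)
    sel = an.selectivity_timecourse(traces, goals, actions)
    np.testing.assert_allclose(sel.goal, 1.0, atol=1e-9)
    np.testing.assert_allclose(sel.action, 0.0, atol=1e-9)
    np.testing.assert_allclose(sel.raw_goal, 8.0, atol=1e-9)


def test_pure_action_coding_yields_action_selectivity_one():
    def rule(p, g, a):
        return 12.0 if an.UNIT_PREFERENCES[p][1] == a else 3.0

    traces, goals, actions = _pattern_trials(rule)
    sel = an.selectivity_timecourse(traces, goals, actions)
    np.testing.assert_allclose(sel.action, 1.0, atol=1e-9)
    np.testing.assert_allclose(sel.goal, 0.0, atol=1e-9)


def test_selectivity_normalization_peak_is_one(scaled_batch):
    b = scaled_batch
    sel = an.selectivity_timecourse([r.trace for r in b.trials],
                                    [r.goal for r in b.trials],
                                    [r.action for r in b.trials])
    peak = max(np.max(np.abs(sel.goal)), np.max(np.abs(sel.action)))
    assert peak == pytest.approx(1.0)


def test_selectivity_rank_deficiency_names_missing_pattern():
    def rule(p, g, a):
        return 5.0

    traces, goals, actions = _pattern_trials(rule)
    # drop every G2/A2 trial
    keep = [i for i, (g, a) in enumerate(zip(goals, actions))
            if not (g == "G2" and a == "A2")]
    with pytest.raises(ValueError, match="G2.*A2"):
        an.selectivity_timecourse([traces[i] for i in keep],
                                  [goals[i] for i in keep],
                                  [actions[i] for i in keep])


def test_batch_selectivity_switches_goal_to_action(scaled_batch):
    """Goal selectivity dominates during the goal epoch, action
    selectivity dominates late, and the detected crossing lies between
    goal onset and the end of the delay period."""
    b = scaled_batch
    sel = an.selectivity_timecourse([r.trace for r in b.trials],
                                    [r.goal for r in b.trials],
                                    [r.action for r in b.trials])
    t = sel.time
    i_goal_peak = np.argmax(sel.goal)
    assert sel.goal[i_goal_peak] > sel.action[i_goal_peak]
    late = (t > 2500) & (t < 3800)
    assert sel.action[late].mean() > 0.8
    assert sel.goal[late].mean() < 0.3
    crossing = an.detect_transition_time(sel)
    assert crossing is not None
    assert 500.0 < crossing < 3000.0


def test_selectivity_and_pc_transition_times_agree(scaled_batch):
    """The batch-level selectivity crossing and the median per-trial
    PC-based transition agree to within 200 ms."""
    b = scaled_batch
    sel = an.selectivity_timecourse([r.trace for r in b.trials],
                                    [r.goal for r in b.trials],
                                    [r.action for r in b.trials])
    t_sel = an.detect_transition_time(sel)
    t_pc = np.median(b.transition_times)
    assert t_sel is not None and b.transition_times.size > 0
    assert abs(t_sel - t_pc) <= 200.0


# ---------------------------------------------------------------------------
# transition detection

def test_step_transition_detected_within_grid_step():
    t = np.arange(0.0, 3000.0)
    t_star = 1400.0
    rates = {}
    for p, (gs, as_) in zip("ABCD", [(1, 1), (1, -1), (-1, -1), (-1, 1)]):
        goal_part = 20.0 * (t < t_star) * (t > 300) * gs
        act_part = 20.0 * (t >= t_star) * as_
        rates[p] = 15.0 + goal_part + act_part
    trace = make_trace(t, rates)
    basis = an.PCBasis(
        components=np.vstack([an.GOAL_CONTRAST, an.ACTION_CONTRAST]),
        rest_offset=np.full(4, 15.0),
        explained_variance_ratio=np.array([0.6, 0.4]),
        goal_axis=0, action_axis=1)
    det = an.detect_transition_time(trace, basis, search_from=0.0)
    assert det == pytest.approx(t_star, abs=1.0)


def test_absent_transition_returns_none():
    t = np.arange(0.0, 3000.0)
    rates = {p: 15.0 + 20.0 * (t > 300) * s
             for p, s in zip("ABCD", (1, 1, -1, -1))}
    trace = make_trace(t, rates)
    basis = an.PCBasis(
        components=np.vstack([an.GOAL_CONTRAST, an.ACTION_CONTRAST]),
        rest_offset=np.full(4, 15.0),
        explained_variance_ratio=np.array([0.9, 0.1]),
        goal_axis=0, action_axis=1)
    assert an.detect_transition_time(trace, basis, search_from=0.0) is None


# ---------------------------------------------------------------------------
# batches

def test_run_batch_reproducible_and_seed_derivation():
    assert an.derive_seed(1, 0) != an.derive_seed(1, 1)
    assert an.derive_seed(1, 0) == an.derive_seed(1, 0)
    assert 0 <= an.derive_seed(12345, 99) < 2 ** 31

    cfg = default_config(n_exc=30, n_inh=30)
    cfg.protocol.trial_duration = 1500.0
    a = an.run_batch(cfg, 2, seed=5)
    b = an.run_batch(cfg, 2, seed=5)
    for ta, tb in zip(a.trials, b.trials):
        assert ta.noise_seed == tb.noise_seed
        np.testing.assert_array_equal(ta.trace.spike_times,
                                      tb.trace.spike_times)
        assert ta.action == tb.action


def test_run_batch_balanced_goals_by_default():
    cfg = default_config(n_exc=30, n_inh=30)
    cfg.protocol.trial_duration = 600.0
    cfg.protocol.goal_display_onset = 550.0
    batch = an.run_batch(cfg, 4, seed=0)
    assert [t.goal for t in batch.trials] == ["G1", "G2", "G1", "G2"]
    counts = batch.pattern_counts
    assert sum(counts.values()) == 4
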