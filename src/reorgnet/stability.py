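"""Fast--slow stability analysis of the mean-field model.

The synaptic activities (time constants <= 100 ms) equilibrate much
faster than the plasticity variables u, x (recovery times 500--1000 ms),
so the slow variables act as bifurcation parameters for the fast
subsystem.  At any moment of a mean-field trajectory the plasticity
state and the external stimulus are frozen, the equilibria of the
5-dimensional fast field (four excitatory activities + the inhibitory
activity) are located by Newton--Raphson iteration from a deterministic
grid of assembly on/off seed patterns, and each equilibrium is
classified by the eigenvalues of a finite-difference Jacobian.  Tracking
the stable set along the trajectory shows the goal attractors dissolve
and the action attractors emerge as the synaptic modulation evolves.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .config import EXC_POPS
from .meanfield import (MeanFieldModel, MeanFieldTrajectory, N_FAST,
                        stationary_activity)

RESIDUAL_TOL = 1e-10     # Newton convergence on the max-norm of the field
REPORT_TOL = 1e-8        # every reported equilibrium satisfies this
DEDUP_TOL = 1e-6         # max-norm distance identifying duplicate roots
STABILITY_EPS = 1e-9     # margin on eigenvalue real parts
FD_STEP = 1e-6           # central-difference Jacobian step


@dataclass
class FrozenSlowState:
    """Plasticity variables and stimulus frozen at one evaluation time."""

    uF: np.ndarray
    xF: np.ndarray
    uD: np.ndarray
    xD: np.ndarray
    g_ext: np.ndarray    # (5,) external conductance per node
    time: float = 0.0

    @classmethod
    def from_trajectory(cls, traj: MeanFieldTrajectory, t: float) -> "FrozenSlowState":
        y = traj.state_at(t)
        protocol = getattr(traj, "protocol", traj.config.protocol)
        g_ext = traj.model.external(protocol, t)
        return cls(uF=y[5:9].copy(), xF=y[9:13].copy(),
                   uD=y[13:17].copy(), xD=y[17:21].copy(),
                   g_ext=g_ext, time=float(t))

    @classmethod
    def resting(cls, model: MeanFieldModel, g_ext=None) -> "FrozenSlowState":
        y = model.resting_state()
        return cls(uF=y[5:9].copy(), xF=y[9:13].copy(),
                   uD=y[13:17].copy(), xD=y[17:21].copy(),
                   g_ext=np.zeros(5) if g_ext is None else np.asarray(g_ext))


@dataclass
class EquilibriumRecord:
    """A fast-subsystem fixed point with its linear stability."""

    location: np.ndarray          # (5,) s_A..s_D, s_I
    eigenvalues: np.ndarray       # complex (5,)
    stable: bool
    marginal: bool
    residual: float
    seed_index: int
    time: float = 0.0

    @property
    def leading_real(self) -> float:
        return float(np.max(self.eigenvalues.real))

    def rates_hz(self, model: MeanFieldModel, frozen: FrozenSlowState) -> np.ndarray:
        """(5,) firing rates at the equilibrium, in Hz."""
        y = _full_state(model, self.location, frozen)
        return model.rates(y, frozen.g_ext) * 1000.0


def _full_state(model: MeanFieldModel, s_fast, frozen: FrozenSlowState):
    y = np.empty(21)
    y[0:4] = s_fast[0:4]
    y[4] = s_fast[4]
    y[5:9] = frozen.uF
    y[9:13] = frozen.xF
    y[13:17] = frozen.uD
    y[17:21] = frozen.xD
    return y


def fast_field(model: MeanFieldModel, s_fast, frozen: FrozenSlowState):
    """Time derivative of the five synaptic activities, slow state frozen."""
    y = _full_state(model, s_fast, frozen)
    r = model.rates(y, frozen.g_ext)
    ds = np.empty(N_FAST)
    ds[0:4] = (stationary_activity(r[:4], model.tau_s_exc)
               - s_fast[0:4]) / model.tau_s_exc
    ds[4] = (stationary_activity(r[4], model.tau_s_inh)
             - s_fast[4]) / model.tau_s_inh
    return ds


def fast_jacobian(model: MeanFieldModel, s_fast, frozen: FrozenSlowState,
                  step: float = FD_STEP) -> np.ndarray:
    """Central finite-difference Jacobian of the fast field."""
    J = np.empty((N_FAST, N_FAST))
    for j in range(N_FAST):
        sp = np.array(s_fast, dtype=float)
        sm = sp.copy()
        sp[j] += step
        sm[j] -= step
        J[:, j] = (fast_field(model, sp, frozen)
                   - fast_field(model, sm, frozen)) / (2 * step)
    return J


def _newton(model, s0, frozen, max_iter: int = 60):
    s = np.array(s0, dtype=float)
    for _ in range(max_iter):
        f = fast_field(model, s, frozen)
        if np.max(np.abs(f)) < RESIDUAL_TOL:
            return s
        J = fast_jacobian(model, s, frozen)
        try:
            delta = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError:
            return None
        # damp very large steps to keep iterates in a sane region
        mx = np.max(np.abs(delta))
        if mx > 0.5:
            delta *= 0.5 / mx
        s = s + delta
        if np.any(~np.isfinite(s)) or np.max(np.abs(s)) > 3.0:
            return None
    f = fast_field(model, s, frozen)
    if np.max(np.abs(f)) < REPORT_TOL:
        return s
    return None


def seed_grid(model: MeanFieldModel, high: float | None = None):
    """Deterministic Newton seeds: all on/off patterns of the four
    excitatory populations crossed with a low/high interneuron guess."""
    if high is None:
        high = float(stationary_activity(model.params.excitatory.r_max / 2,
                                         model.tau_s_exc))
    high_I = float(stationary_activity(model.params.inhibitory.r_max / 2,
                                       model.tau_s_inh))
    seeds = []
    for bits in itertools.product((0.0, 1.0), repeat=4):
        for s_I in (0.0, high_I):
            s = np.array([b * high for b in bits] + [s_I])
            seeds.append(s)
    return seeds


def find_equilibria(model: MeanFieldModel, frozen: FrozenSlowState,
                    seeds=None) -> list:
    """Locate and classify all fast-subsystem equilibria found from the
    seed grid.  Converged roots are deduplicated (max-norm tolerance)
    and classified by the eigenvalues of the finite-difference Jacobian;
    eigenvalues within ``STABILITY_EPS`` of the imaginary axis mark the
    record as marginal."""
    if seeds is None:
        seeds = seed_grid(model)
    records = []
    for i, s0 in enumerate(seeds):
        root = _newton(model, s0, frozen)
        if root is None:
            continue
        if any(np.max(np.abs(root - r.location)) < DEDUP_TOL for r in records):
            continue
        J = fast_jacobian(model, root, frozen)
        eig = np.linalg.eigvals(J)
        max_re = np.max(eig.real)
        records.append(EquilibriumRecord(
            location=root,
            eigenvalues=eig,
            stable=bool(max_re < -STABILITY_EPS),
            marginal=bool(abs(max_re) <= STABILITY_EPS),
            residual=float(np.max(np.abs(fast_field(model, root, frozen)))),
            seed_index=i,
            time=frozen.time,
        ))
    records.sort(key=lambda r: tuple(np.round(r.location, 6)))
    return records


@dataclass
class AttractorTimeline:
    """Stable-equilibrium sets sampled along a mean-field trajectory."""

    times: np.ndarray
    records: list                      # list (per time) of EquilibriumRecord lists
    projections: list | None = None    # per time: (n_stable, n_pc) PC coords

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(r.stable for r in recs) for recs in self.records])

    def to_frame(self, basis=None):
        import pandas as pd
        rows = []
        for t, recs, projs in zip(self.times, self.records,
                                  self.projections or [None] * len(self.times)):
            stable_idx = 0
            for r in recs:
                row = {"time_ms": t, "stable": r.stable,
                       "marginal": r.marginal,
                       "leading_re": r.leading_real,
                       "residual": r.residual}
                for j, p in enumerate(EXC_POPS):
                    row[f"s_{p}"] = r.location[j]
                row["s_IN"] = r.location[4]
                if r.stable and projs is not None:
                    row["pc_goal"] = projs[stable_idx][0]
                    row["pc_action"] = projs[stable_idx][1]
                    stable_idx += 1
                rows.append(row)
        return pd.DataFrame(rows)


def track_attractors(traj: MeanFieldTrajectory, stride: float = 20.0,
                     basis=None, times=None) -> AttractorTimeline:
    """Find the equilibrium set at frozen slow states sampled along a
    trajectory.

    With a fitted PC ``basis`` (see :func:`reorgnet.analysis.fit_pca`),
    each stable equilibrium is also projected, via its population rates,
    onto the (goal-axis, action-axis) plane.
    """
    model = traj.model
    if times is None:
        times = np.arange(traj.time[0], traj.time[-1] + stride / 2, stride)
    all_records = []
    all_proj = [] if basis is not None else None
    for t in times:
        frozen = FrozenSlowState.from_trajectory(traj, float(t))
        recs = find_equilibria(model, frozen)
        all_records.append(recs)
        if basis is not None:
            proj = []
            for r in recs:
                if not r.stable:
                    continue
                rates = r.rates_hz(model, frozen)[:4]
                pc = basis.project(rates)
                proj.append((float(pc[basis.goal_axis]),
                             float(pc[basis.action_axis])))
            all_proj.append(proj)
    return AttractorTimeline(times=np.asarray(times, dtype=float),
                             records=all_records, projections=all_proj)
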