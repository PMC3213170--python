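"""Reproducible experiment protocols and parameter sweeps.

Each experiment writes, under its output directory: the exact
configuration snapshot (YAML), the derived per-trial seeds, the trial
summary table, and the relevant traces, so a run is reproducible
bit-for-bit from the snapshot and master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import analysis
from .config import (ACTION_ASSEMBLIES, NetworkConfig, default_config,
                     save_config, validate_config)
from .meanfield import simulate_mean_field
from .stability import track_attractors

EXPERIMENT_NAMES = (
    "baseline", "no_plasticity", "perturbation_sweep", "activation_sweep",
    "asymmetry_sweep", "meanfield_stability", "variant_dep", "variant_fac",
)

#: default perturbation amplitude (nS) for the perturbation experiments:
#: an order of magnitude below the sensory input, so the pulse probes the
#: stability of an established goal state instead of steering the initial
#: ignition straight into an action attractor
PERTURBATION_AMPLITUDE = 0.03


@dataclass
class ExperimentSpec:
    """What to run and where to put it."""

    name: str
    n_trials: int = 40
    seed: int = 0
    fast: bool = False            # scaled-down mode: N=50, 8 trials
    out_dir: str | Path | None = None
    overrides: dict = field(default_factory=dict)
    axis_values: list | None = None
    trials_per_value: int = 10
    overwrite: bool = False
    write_traces: bool = True

    def __post_init__(self):
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}; "
                             f"choose from {EXPERIMENT_NAMES}")


def _apply_overrides(cfg: NetworkConfig, overrides: dict) -> NetworkConfig:
    """Apply a flat dotted-path override patch, e.g.
    ``{"protocol.activation_amplitude": 0.5}``."""
    cfg = cfg.copy()
    for path, value in overrides.items():
        obj = cfg
        parts = path.split(".")
        for p in parts[:-1]:
            obj = getattr(obj, p)
        if not hasattr(obj, parts[-1]):
            raise AttributeError(f"override {path!r}: no such field")
        setattr(obj, parts[-1], value)
    return validate_config(cfg)


def base_config(spec: ExperimentSpec) -> NetworkConfig:
    variant = {"variant_dep": "depression_only",
               "variant_fac": "facilitation_only"}.get(spec.name, "all_types")
    n = 50 if spec.fast else 200
    cfg = default_config(variant=variant, n_exc=n, n_inh=n, seed=spec.seed)
    return _apply_overrides(cfg, spec.overrides)


def _prepare_out(spec: ExperimentSpec) -> Path | None:
    if spec.out_dir is None:
        return None
    out = Path(spec.out_dir)
    if out.exists() and any(out.iterdir()) and not spec.overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty (pass overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    return out


def scale_action_weights(cfg: NetworkConfig, ratio: float,
                         target: str = "A1") -> NetworkConfig:
    """Scale the summed weight of one action assembly's mutual synapses."""
    cfg = cfg.copy()
    a, b = ACTION_ASSEMBLIES[target]
    for conn in cfg.connections:
        if {conn.pre_pop, conn.post_pop} == {a, b}:
            conn.summed_weight *= ratio
    return cfg


def run_experiment(spec: ExperimentSpec):
    """Run one named experiment; returns the result object and writes the
    bundle to ``spec.out_dir`` when given."""
    out = _prepare_out(spec)
    if spec.name in ("baseline", "no_plasticity", "variant_dep", "variant_fac"):
        cfg = base_config(spec)
        n_trials = 8 if (spec.fast and spec.n_trials == 40) else spec.n_trials
        batch = analysis.run_batch(
            cfg, n_trials, spec.seed,
            frozen_plasticity=(spec.name == "no_plasticity"))
        if out is not None:
            _write_batch(out, spec, cfg, batch)
        return batch
    if spec.name.endswith("_sweep"):
        axis = {"perturbation_sweep": "perturbation_onset",
                "activation_sweep": "activation_amplitude",
                "asymmetry_sweep": "asymmetry_ratio"}[spec.name]
        return sweep(spec, axis=axis)
    if spec.name == "meanfield_stability":
        return meanfield_stability_run(spec)
    raise AssertionError(spec.name)


def _write_batch(out: Path, spec: ExperimentSpec, cfg: NetworkConfig, batch):
    save_config(cfg, out / "config.yaml")
    batch.summary_frame().to_csv(out / "trials.csv", index=False)
    summary = {
        "experiment": spec.name,
        "master_seed": spec.seed,
        "n_trials": len(batch.trials),
        "pattern_counts": {f"{g}/{a}": n
                           for (g, a), n in batch.pattern_counts.items()},
        "transition_stats": batch.transition_stats(),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    if spec.write_traces:
        tdir = out / "traces"
        tdir.mkdir(exist_ok=True)
        for i, tr in enumerate(batch.trials):
            tr.trace.to_frame().to_csv(tdir / f"trial_{i:03d}.csv", index=False)


DEFAULT_AXES = {
    "perturbation_onset": [200.0, 500.0, 800.0],         # ms after goal onset
    "activation_amplitude": [0.30, 0.35, 0.40],          # nS
    "asymmetry_ratio": [1.0, 1.05, 1.10],                # A&D weight factor
}


@dataclass
class SweepResult:
    axis: str
    values: list
    rows: list                     # dict per value
    batches: list = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)


def sweep(spec: ExperimentSpec, axis: str) -> SweepResult:
    """Parameter sweep over perturbation onset, activation amplitude or
    action-assembly asymmetry; per value reports median/SD transition
    time and (for asymmetry) the selection ratio toward the strengthened
    assembly."""
    values = spec.axis_values or DEFAULT_AXES[axis]
    if len(values) < 3:
        raise ValueError("a sweep needs at least 3 axis values")
    out = _prepare_out(spec)
    rows, batches = [], []
    for j, v in enumerate(values):
        cfg = base_config(spec)
        if axis == "perturbation_onset":
            cfg.protocol.perturbation_amplitude = PERTURBATION_AMPLITUDE
            cfg.protocol.perturbation_onset = float(v)
            cfg.protocol.perturbation_target = "A1"
        elif axis == "activation_amplitude":
            cfg.protocol.activation_amplitude = float(v)
        elif axis == "asymmetry_ratio":
            cfg = scale_action_weights(cfg, float(v), "A1")
        else:
            raise ValueError(f"unknown sweep axis {axis!r}")
        batch = analysis.run_batch(cfg, spec.trials_per_value,
                                   analysis.derive_seed(spec.seed, 1000 + j))
        tt = batch.transition_times
        sel = [t.action for t in batch.trials]
        row = {
            "axis": axis, "value": v,
            "n_trials": len(batch.trials),
            "n_transitions": int(tt.size),
            "median_transition_ms": float(np.median(tt)) if tt.size else None,
            "mean_transition_ms": float(tt.mean()) if tt.size else None,
            "sd_transition_ms": float(tt.std(ddof=1)) if tt.size > 1 else None,
            "selection_ratio_A1": (sel.count("A1") / len(sel) if sel else None),
        }
        if axis == "perturbation_onset":
            onset_abs = cfg.protocol.goal_display_onset + v
            lat = [t.transition_ms - onset_abs for t in batch.trials
                   if t.transition_ms is not None
                   and t.transition_ms >= onset_abs]
            row["median_latency_after_perturbation_ms"] = (
                float(np.median(lat)) if lat else None)
        rows.append(row)
        batches.append(batch)
    result = SweepResult(axis=axis, values=list(values), rows=rows,
                         batches=batches)
    if out is not None:
        save_config(base_config(spec), out / "config.yaml")
        result.to_frame().to_csv(out / "sweep.csv", index=False)
        (out / "summary.json").write_text(json.dumps(
            {"experiment": spec.name, "axis": axis,
             "master_seed": spec.seed, "rows": rows}, indent=2))
    return result


def meanfield_stability_run(spec: ExperimentSpec):
    """Mean-field trajectory, its PC projection and the attractor timeline."""
    out = _prepare_out(spec)
    cfg = base_config(spec)
    # all four goal x action patterns, so the fitted PC axes are the
    # symmetric goal / action contrasts
    trajs = {}
    for goal in ("G1", "G2"):
        for target in ("A1", "A2"):
            c = cfg.copy()
            c.protocol.sensory_target = goal
            trajs[(goal, target)] = simulate_mean_field(c, symmetry_break=target)
    traj_g1 = trajs[("G1", "A1")]
    basis = analysis.fit_pca(list(trajs.values()))
    timeline = track_attractors(traj_g1, stride=50.0, basis=basis)
    if out is not None:
        save_config(cfg, out / "config.yaml")
        for (goal, target), tr in trajs.items():
            tr.to_frame().to_csv(out / f"meanfield_{goal}_{target}.csv",
                                 index=False)
        timeline.to_frame().to_csv(out / "attractors.csv", index=False)
        (out / "summary.json").write_text(json.dumps({
            "experiment": spec.name,
            "master_seed": spec.seed,
            "stable_counts": timeline.stable_counts().tolist(),
            "times_ms": timeline.times.tolist(),
        }, indent=2))
    return traj_g1, timeline, basis
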