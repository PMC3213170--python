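# reorgnet

Simulation and analysis of a **dynamically reorganizable attractor
network** of prefrontal cortex: a spiking circuit whose cell assemblies
are rebuilt on the fly by short-term synaptic plasticity, so that the
network's persistent activity switches *endogenously* — with no external
trigger — from representing a **goal** to representing an **action**
during the delay period of an action-planning task.

The package is aimed at computational neuroscientists who want to
simulate, reduce and analyze this class of working-memory circuits: it
provides the spiking simulator, a deterministic mean-field reduction, a
fast–slow bifurcation-tracking stability analysis, and the selectivity /
principal-component analyses used to quantify representational
switching.

## The model

Four excitatory populations A–D (200 leaky integrate-and-fire neurons
each) and one pool of 200 inhibitory interneurons are sparsely connected
(connectivity ratio c = 0.2). Pairs A&B and C&D are wired as
goal-coding assemblies through **depressing** synapses (summed weight
3.2 nS), pairs A&D and B&C as action-coding assemblies through
**facilitating** synapses (1.55 nS); self-recurrent and inhibitory
synapses are constant. Each membrane follows

    C_m dV/dt = −g_L (V − V_L) − g_E (V − V_E) − g_I (V − V_I) + noise,

with conductance-based synapses whose activity *s* is set by each
presynaptic spike to the release peak *u·x* of the Tsodyks–Markram
plasticity variables (utilization *u*, resources *x*; *U* = 0.2, decay
constants 20/600 ms for depression and 600/100 ms for facilitation) and
decays with τ = 100 ms (NMDA-like) or 20 ms (inhibitory).

Displaying a goal (a 0.2 nS sensory pulse plus a 0.35 nS common
activation ramp) ignites the corresponding goal assembly. Its own
activity then depresses the goal synapses while facilitating the action
synapses, so after roughly one second the goal attractor dissolves and
the state falls into one of the two newly dominant action assemblies —
the representational switch. The mean-field reduction
(Naka–Rushton transfer functions fitted to the spiking neurons, M = 2)
makes this visible as a bifurcation sequence: the plasticity variables
act as slowly moving bifurcation parameters that first destabilize the
goal attractor and then carve out the two action attractors.

## Worked example

```python
import numpy as np
import reorgnet as rn
from reorgnet import analysis, meanfield, stability

cfg = rn.default_config()                      # all-types wiring, N = 200
batch = analysis.run_batch(cfg, 8, seed=1, goals=["G1"] * 8)
print("patterns:", batch.pattern_counts)
print("median transition (ms):", np.median(batch.transition_times))
print("median dwell (s):", round(np.median(batch.dwell_times) / 1000, 3))

model = meanfield.MeanFieldModel(cfg)
frozen = stability.FrozenSlowState.resting(model)
stable = [r for r in stability.find_equilibria(model, frozen) if r.stable]
print("stable equilibria at rest:", len(stable))
```

prints

```
patterns: {('G1', 'A2'): 3, ('G1', 'A1'): 5}
median transition (ms): 1675.0
median dwell (s): 0.822
stable equilibria at rest: 5
```

Eight trials with goal G1 all switch to an action state (5 chose action
A1 = A&D, 3 chose A2 = B&C — the symmetric actions are picked by noise);
the median switch happens 1.18 s after the goal display at 0.5 s, after
a median dwell of 0.82 s on the goal axis. At resting plasticity the
reduced model is multistable: the silent state, both goal states, and
both (weaker) action states; the goal display collapses this set to the
selected goal state, and after the switch exactly two attractors remain
on the action axis (`stability.track_attractors` tabulates the full
timeline).

## Command line

```bash
reorgnet run   --out out/baseline --trials 40 --seed 1     # trial batch
reorgnet run   --out out/ctrl --no-plasticity --fast       # frozen-synapse control
reorgnet sweep --out out/pert --axis perturbation_onset    # Fig-style sweeps
reorgnet stability --out out/mf                            # mean-field + attractor timeline
reorgnet fitrate --out rate_params.json                    # refit transfer functions
```

Every run writes its exact configuration snapshot, derived seeds and
result tables, and is bit-for-bit reproducible from them.

## Layout

| module | contents |
| --- | --- |
| `reorgnet.config` | parameter schema, the three canonical wirings, validation, YAML I/O |
| `reorgnet.network` | random connectivity construction (exact in-degree, uniform delays) |
| `reorgnet.spiking` | vectorized LIF + short-term-plasticity simulator, rates, efficacies |
| `reorgnet.meanfield` | transfer-function fitting and the 21-dimensional rate model |
| `reorgnet.stability` | Newton–Raphson equilibrium search, eigenvalue classification, attractor tracking |
| `reorgnet.analysis` | PCA state space, dummy-variable selectivity, transition times, batches |
| `reorgnet.experiments` / `reorgnet.cli` | named protocols, parameter sweeps, command line |
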