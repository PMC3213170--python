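# Methods

This note records the model, the conventions the implementation commits
to, the reasoning behind choices that the source description left open,
and the limits of what the test suite shows.

## Spiking network

**Neurons.** Leaky integrate-and-fire with conductance-based synapses.

| quantity | excitatory | inhibitory | unit |
| --- | --- | --- | --- |
| membrane capacitance C_m | 0.5 | 0.2 | nF |
| leak conductance g_L | 25 | 20 | nS |
| leak reversal V_L | −70 | −65 | mV |
| threshold / reset | −52 / −60 | −52 / −60 | mV |
| refractory period | 2 | 1 | ms |
| exc. / inh. reversal | −5 / −75 | −5 / −75 | mV |
| bias conductance | 8.35 | 4.0 | nS |

With the bias alone the excitatory membrane rests at
(25·(−70)+8.35·(−5))/33.35 ≈ −53.7 mV, just below threshold: all firing
at rest is noise-driven.

**Noise.** An independent normal deviate of standard deviation
σ·√dt is added to every non-refractory membrane potential each step
(Euler–Maruyama convention; σ in mV/√ms). σ is the one free parameter
of the model — its printed value did not survive into our sources — and
is calibrated once to two qualitative anchors: the resting excitatory
population fires below 1 Hz over a full 4 s trial, and the goal-state
dwell before the endogenous switch is about one second. The default is
**σ = 0.14 mV/√ms**. The usable corridor is narrow: below ≈0.13 the
goal assembly fails to ignite within the trial; above ≈0.17 the resting
state ignites spontaneously.

**Synapses.** Each excitatory neuron owns three synaptic-activity
variables (facilitation, depression, constant kind), shared by all its
efferent synapses of that kind; interneurons own one. A presynaptic
spike sets the activity to its release peak; between spikes activities
decay exponentially (τ = 100 ms for all excitatory kinds — only the
slow, NMDA-like component is modeled — and 20 ms for inhibition).
Release peaks: 1 for constant kinds; u·x for plastic kinds, with the
per-spike update applied in the order

    u ← u + U (1 − u);   peak = u·x;   x ← x − peak

and relaxation u → U (τ_u), x → 1 (τ_x) between spikes. Kind
constants: U = 0.2 for both; depression τ_u = 20 ms, τ_x = 600 ms
(utilization recovers fast, resources slowly); facilitation
τ_u = 600 ms, τ_x = 100 ms. This assignment of the four printed time
constants is the only one that uses all four values and makes the two
kinds net-depressing and net-facilitating respectively.

**Connectivity.** Every neuron receives exactly round(c·N_pre)
presynaptic partners per incoming class (c = 0.2), drawn uniformly
without replacement, autapses excluded; per-synapse weight
W/(c·N_pre); transmission delays uniform on [1, 5] ms, quantized to the
integration step at simulation time. Summed weights per wiring:

| class | all-types | depression-only | facilitation-only |
| --- | --- | --- | --- |
| goal (A↔B, C↔D) | 3.2 (dep.) | 3.0 (dep.) | 0.8 (const.) |
| action (A↔D, B↔C) | 1.55 (fac.) | 0.5 (const.) | 3.1 (fac.) |
| self-recurrent | 1.7 | 1.8 | 1.9 |
| E → IN | 0.7 | 0.7 | 0.7 |
| IN → E | 5.0 | 5.5 | 7.5 |

**Integration.** Classical fixed-step RK4 at dt = 0.1 ms, conductances
held constant within a step. Threshold is checked after each step
(noise included); spikes are timestamped at the step end, the membrane
is clamped at reset for the refractory period. Delayed delivery is
exact: each synapse deposits weight·(peak − s_before) into its target's
aggregated conductance one delay after the spike, and the aggregate
decays with the same time constant as the activities, so the aggregate
equals the delayed per-synapse sum identically. A scalar event-driven
reference implementation (per-synapse state, explicit event lists)
reproduces the vectorized simulator spike-for-spike on a noise-free
10-neuron fixture.

**Stimuli.** Activation: linear ramp 0 → 0.35 nS over 200 ms from the
goal-display onset, then held, on A–D. Sensory: 0.2 nS × 200 ms
rectangular pulse on the displayed goal's assembly. Optional
perturbation: rectangular pulse on one action assembly. Default trial
timeline (the source gives stimulus widths but no absolute timeline):
goal display at 0.5 s, trial end 4.0 s, nominal Go signal at 3.0 s used
by "switch precedes the Go" checks.

**Read-out and labels.** A1 activity = rate(A) + rate(D), A2 =
rate(B) + rate(C). A trial's selected action is the read-out that
exceeds twice the other continuously through the final 200 ms of the
trial — i.e. the attractor the network has converged to. (An earlier
"first sustained dominance" rule mislabels trials: asymmetric ignition
of a goal assembly can transiently make one read-out dominant.)

## Derived measures

**Principal components.** Rates of the four excitatory populations,
kernel-smoothed (Gaussian, 50 ms), rest-centered by subtracting the
pre-onset mean, PCA over pooled trial samples. Components are
relabeled as the *goal axis* / *action axis* by their alignment with the
architectural contrasts (A+B−C−D)/2 and (A+D−B−C)/2, with signs fixed so
G1 and action A1 project positive. Variance ordering alone is not used
for labeling: in long trials most variance lies along the action axis
(the action state occupies most of the trial), so the goal axis is not
always the first component.

**Selectivity.** At each time step, ordinary least squares of a unit's
rate across trials on an intercept, a goal dummy (1 = trial's goal is
the unit's preferred goal) and an action dummy. Preferences follow the
architecture (A: G1/A1, B: G1/A2, C: G2/A2, D: G2/A1). The default
"unit" is the average of the four populations' coefficient time courses;
both series are normalized by their joint maximum absolute value.

**Transition and dwell times.** Switch = first time the action measure
exceeds the goal measure, sustained 200 ms, *and* exceeds 20 % of its
own trial maximum (the floor suppresses spurious detections in the
near-zero epoch before ignition). Goal entry = first time the goal-axis
projection is dominant and above half its trial maximum, sustained
100 ms. Dwell = entry → switch. The batch-level selectivity crossing
and the median per-trial PC switch agree within 200 ms on the batches in
the test suite.

## Mean-field reduction

State (21 dimensions): one constant-kind mean activity per excitatory
population, one inhibitory activity, and mean u, x per population for
each plastic kind. Rates are algebraic in the conductances through a
Naka–Rushton transfer function per neuron class,

    r = r_max [g_E − c_I·g_I − θ]₊² / (h² + [g_E − c_I·g_I − θ]₊²),

fitted (separately for the excitatory and inhibitory class) to rates of
uncoupled pools of the spiking neurons under clamped conductances. The
fit uses relative-error weighting (1/(r + 5 Hz)) on a grid refined
around the firing onset: the onset region decides the fixed-point
structure of the reduced network, and an unweighted fit that tolerates a
few Hz of error at the resting bias destroys the resting fixed point
altogether. Packaged defaults (`reorgnet/data/rate_params.json`, with
residuals): excitatory r_max = 105 Hz, θ = 8.34 nS, h = 3.20 nS,
c_I = 0.458; inhibitory r_max = 182 Hz, θ = 4.89 nS, h = 1.80 nS,
c_I = 0.476.

Reconstructed pieces (their printed forms did not survive):

- stationary synaptic activity s∞(r) = ρ(1 − e^(−1/ρ)), ρ = r·τ_s — the
  time average of a set-to-peak synapse under a *regular* spike train.
  Driven LIF neurons fire quasi-regularly, and this form gives the
  reduction measurably more competitive gain than the Poisson average
  ρ/(1+ρ); with the Poisson form the reduced network settles into a
  stable homogeneous state and never switches.
- ds/dt = (s∞(r) − s)/τ_s; du/dt = (U−u)/τ_u + U(1−u)r;
  dx/dt = (1−x)/τ_x − u⁺xr with u⁺ = u + U(1−u) (matching the spiking
  update order).
- a plastic class contributes activity s·u·x — the constant-kind mean
  scaled by the release peak — so at rest it is U (= 5×) weaker than a
  constant synapse of equal summed weight, exactly as in the spiking
  model.

The goal-assembly weight is reduced to 1.9 nS in the mean-field copy of
the all-types wiring (spiking fluctuations let the noisy network escape
the goal state earlier; the weaker deterministic coupling restores a
comparable switch time). A perfectly symmetric deterministic run stays
on the action saddle forever, so trials apply the canonical
0.01 nS × 200 ms pulse to one action assembly at goal onset; which
assembly receives it determines the selected action.

Integration: adaptive RK45, rtol 1e−8, atol 1e−10, max step 25 ms.

## Stability analysis

Fast–slow decomposition: activities (τ ≤ 100 ms) are fast, u and x
(effective recovery 500–1000 ms) are slow. At an evaluation time the
slow state *and the external stimulus* are frozen; the 5-dimensional
fast field is solved by damped Newton–Raphson from 32 deterministic
seeds (all on/off patterns of the four excitatory populations × low/high
interneuron guess), roots deduplicated at 1e−6 (max norm) and classified
by the eigenvalues of a central finite-difference Jacobian (step 1e−6;
stability margin 1e−9 on real parts, near-axis roots flagged marginal;
every reported root has residual < 1e−8). Attractor timelines sample a
trajectory at a fixed stride and project each stable equilibrium's
rates onto a PC basis fitted to the four mean-field transition patterns
(two goals × two pulse targets) — a basis fitted to fewer patterns
polarizes the action axis toward one action and misplaces the mirrored
attractor.

## Experiment defaults and problem sizes

- Baseline batches: 40 trials at full size (200 neurons/population),
  goals alternating. Scaled-down mode for quick runs and most tests:
  50 neurons/population, 8–16 trials; at this size trial-to-trial
  variability is larger, single networks carry a noticeable quenched
  selection bias (coverage tests redraw the connectivity per trial), and
  a minority of trials ignite the wrong goal first.
- Perturbation experiments: amplitude 0.03 nS (not printed in the
  source; chosen an order of magnitude below the sensory input so the
  pulse probes the stability of an *established* goal state — at
  0.1 nS an early pulse steers the ignition itself straight into an
  action attractor and all latencies collapse to zero), onsets
  200/500/800 ms after goal onset, full-size trials.
- Activation sweep: 0.30/0.35/0.40 nS. Asymmetry sweep: A&D summed
  weight × 1.0/1.05/1.10.
- The dwell-time measurement and the acceptance script use 8 full-size
  G1 trials; the test suite runs in roughly 15 minutes on one CPU.

## What the generator does and does not emulate

All data are generated by the model itself; there is no recorded data
in the package. The synthetic trials share the uniform parameters of
the model: every neuron in a population is statistically identical, so
the diversity of real prefrontal responses (mixed selectivity, a range
of switch times and partial switches across cells) is absent, and
selectivity curves are sharper than recorded ones. Passing tests show
that the *mechanism* — assembly reorganization by short-term plasticity
— behaves as described under these idealized conditions, not that the
parameters reproduce any particular recorded neuron.

## Known limitations

- **Five attractors at rest, not three.** With the printed weights the
  action assemblies are also self-sustaining at resting plasticity:
  freezing u, x at rest in the *spiking* network and kicking A&D leaves
  it persistently active near 20 Hz, and the reduced model agrees
  (action states at ≈20 Hz, goal states at ≈27 Hz). The resting
  attractor set is therefore {rest, 2 goal, 2 action}; the acceptance
  test asserting exactly three stable attractors fails and is left
  failing. The rest of the claimed sequence is intact: the goal display
  collapses the set to the selected goal state, and after the switch
  exactly two attractors lie on the action axis.
- **Activation amplitude advances (not delays) the switch.** Stronger
  common activation raises the goal-state rate (faster depression) and
  depolarizes the silent action populations (faster noise escape into
  the pre-existing action attractors), so the median transition time
  *decreases* along the amplitude axis at every size and noise level
  tested. The corresponding trend test fails and is left failing.
- **Wrong-goal interludes.** In many trials the unused goal assembly
  ignites transiently between the collapse of the displayed goal state
  and the capture by an action state (its synapses are still fresh while
  the displayed assembly's are depressed). The state stays on the goal
  axis — dwell times are unaffected — but batch-level goal selectivity
  peaks well below the action selectivity peak.
- The printed transfer-function coefficients could not be used: the
  excitatory and inhibitory rows are typeset identically (an interneuron
  with the excitatory threshold could never fire at its 4 nS bias), and
  under the most plausible symbol assignment the excitatory curve is too
  shallow at onset for the network to ignite at all. They are kept as
  non-binding reference values.
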