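populations:
  A:
    size: 200
    neuron:
      membrane_capacitance: 0.5
      leak_conductance: 25.0
      leak_reversal: -70.0
      threshold: -52.0
      reset: -60.0
      refractory: 2.0
      excitatory_reversal: -5.0
      inhibitory_reversal: -75.0
      noise_sigma: 0.14
    bias_conductance: 8.35
  B:
    size: 200
    neuron:
      membrane_capacitance: 0.5
      leak_conductance: 25.0
      leak_reversal: -70.0
      threshold: -52.0
      reset: -60.0
      refractory: 2.0
      excitatory_reversal: -5.0
      inhibitory_reversal: -75.0
      noise_sigma: 0.14
    bias_conductance: 8.35
  C:
    size: 200
    neuron:
      membrane_capacitance: 0.5
      leak_conductance: 25.0
      leak_reversal: -70.0
      threshold: -52.0
      reset: -60.0
      refractory: 2.0
      excitatory_reversal: -5.0
      inhibitory_reversal: -75.0
      noise_sigma: 0.14
    bias_conductance: 8.35
  D:
    size: 200
    neuron:
      membrane_capacitance: 0.5
      leak_conductance: 25.0
      leak_reversal: -70.0
      threshold: -52.0
      reset: -60.0
      refractory: 2.0
      excitatory_reversal: -5.0
      inhibitory_reversal: -75.0
      noise_sigma: 0.14
    bias_conductance: 8.35
  IN:
    size: 200
    neuron:
      membrane_capacitance: 0.2
      leak_conductance: 20.0
      leak_reversal: -65.0
      threshold: -52.0
      reset: -60.0
      refractory: 1.0
      excitatory_reversal: -5.0
      inhibitory_reversal: -75.0
      noise_sigma: 0.14
    bias_conductance: 4.0
connections:
- pre_pop: A
  post_pop: B
  kind: constant
  summed_weight: 0.8
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: B
  post_pop: A
  kind: constant
  summed_weight: 0.8
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: C
  post_pop: D
  kind: constant
  summed_weight: 0.8
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: D
  post_pop: C
  kind: constant
  summed_weight: 0.8
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: A
  post_pop: D
  kind: facilitation
  summed_weight: 3.1
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: D
  post_pop: A
  kind: facilitation
  summed_weight: 3.1
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: B
  post_pop: C
  kind: facilitation
  summed_weight: 3.1
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: C
  post_pop: B
  kind: facilitation
  summed_weight: 3.1
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: A
  post_pop: A
  kind: constant
  summed_weight: 1.9
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: B
  post_pop: B
  kind: constant
  summed_weight: 1.9
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: C
  post_pop: C
  kind: constant
  summed_weight: 1.9
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: D
  post_pop: D
  kind: constant
  summed_weight: 1.9
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: A
  post_pop: IN
  kind: constant
  summed_weight: 0.7
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: B
  post_pop: IN
  kind: constant
  summed_weight: 0.7
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: C
  post_pop: IN
  kind: constant
  summed_weight: 0.7
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: D
  post_pop: IN
  kind: constant
  summed_weight: 0.7
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: IN
  post_pop: A
  kind: inhibitory
  summed_weight: 7.5
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: IN
  post_pop: B
  kind: inhibitory
  summed_weight: 7.5
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: IN
  post_pop: C
  kind: inhibitory
  summed_weight: 7.5
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
- pre_pop: IN
  post_pop: D
  kind: inhibitory
  summed_weight: 7.5
  connectivity_ratio: 0.2
  delay_range:
  - 1.0
  - 5.0
plasticity:
  depression:
    U_rest: 0.2
    tau_u: 20.0
    tau_x: 600.0
  facilitation:
    U_rest: 0.2
    tau_u: 600.0
    tau_x: 100.0
protocol:
  activation_amplitude: 0.35
  activation_ramp: 200.0
  sensory_amplitude: 0.2
  sensory_width: 200.0
  sensory_target: G1
  perturbation_amplitude: 0.0
  perturbation_onset: 0.0
  perturbation_width: 200.0
  perturbation_target: A1
  goal_display_onset: 500.0
  trial_duration: 4000.0
variant: facilitation_only
seed: 0
dt: 0.1
tau_s_exc: 100.0
tau_s_inh: 20.0
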