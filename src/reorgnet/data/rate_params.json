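{
  "excitatory": {
    "r_max": 0.10533793068670891,
    "theta": 8.339586299131785,
    "h": 3.2044743244271734,
    "c_inh": 0.4583580998316544,
    "M": 2.0
  },
  "inhibitory": {
    "r_max": 0.1822370468135516,
    "theta": 4.894158301145339,
    "h": 1.796964953351122,
    "c_inh": 0.4764121468991696,
    "M": 2.0
  },
  "residual_rms": {
    "excitatory": 0.005214947427559689,
    "inhibitory": 0.015009125644009408
  }
}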