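name: chronic_convergence
description: >
  Long chronic burst schedule (20-30 min of bursts every ~35 s) used for
  population set-point convergence: Gsyn/Gin ratios converge toward the
  attractor from either side.
drive: nerve
n_bursts: 40
pulses_per_burst: 60
hz: 30.0
interval_s: 35.0
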