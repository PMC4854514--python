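name: curare_no_burst
description: >
  Curare application without presynaptic stimulation: no synaptic events,
  no calcium signals, no plasticity.
drive: none
n_bursts: 3
pulses_per_burst: 5
hz: 30.0
interval_s: 30.0
curare_factor: 0.05
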