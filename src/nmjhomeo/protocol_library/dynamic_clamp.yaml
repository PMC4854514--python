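name: dynamic_clamp
description: >
  Input conductance raised by dynamic-clamp injection of passive leak plus
  inward-rectifier conductances (scaled to the reference cell), keeping
  synaptic events subthreshold during the conditioning bursts -> LTP.
drive: nerve
n_bursts: 3
pulses_per_burst: 5
hz: 30.0
interval_s: 30.0
dc_gleak: 250.0
dc_gkir: 60.0
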