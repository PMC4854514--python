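name: curare_ryanodine
description: >
  Subthreshold (curare) bursts in a ryanodine-loaded cell: potentiation is
  unchanged because subthreshold events never recruit DICR anyway.
drive: nerve
n_bursts: 3
pulses_per_burst: 5
hz: 30.0
interval_s: 30.0
curare_factor: 0.05
ryanodine: true
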