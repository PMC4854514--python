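name: direct_ap
description: >
  Muscle action potentials triggered by direct current steps without any
  presynaptic activity: DICR alone -> long-term depression.
drive: muscle
n_bursts: 3
pulses_per_burst: 5
hz: 30.0
interval_s: 30.0
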