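name: ryanodine
description: >
  Suprathreshold synaptic bursts with the sarcoplasmic-reticulum release
  blocked by ryanodine: muscle spikes occur but produce no DICR, so the
  nicotinic signal potentiates without restraint.
drive: nerve
n_bursts: 3
pulses_per_burst: 5
hz: 30.0
interval_s: 30.0
ryanodine: true
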