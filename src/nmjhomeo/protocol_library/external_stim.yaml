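name: external_stim
description: >
  External stimulation firing both the nerve and the muscle directly; with
  external Ca2+ present both calcium signals are engaged and the synapse is
  stable.
drive: external
n_bursts: 15
pulses_per_burst: 40
hz: 30.0
interval_s: 40.0
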