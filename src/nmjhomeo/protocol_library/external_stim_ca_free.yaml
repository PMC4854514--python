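name: external_stim_ca_free
description: >
  External stimulation in Ca2+-free medium: muscle still spikes but no
  transmitter is released, isolating DICR -> depression.
drive: external
n_bursts: 15
pulses_per_burst: 40
hz: 30.0
interval_s: 40.0
ca_free: true
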