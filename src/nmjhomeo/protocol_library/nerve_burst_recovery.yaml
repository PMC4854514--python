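name: nerve_burst_recovery
description: >
  Nerve-burst stimulation applied after a depression episode; the
  homeostatic drive potentiates the weakened synapse back toward the set
  point (partial recovery).
drive: nerve
n_bursts: 6
pulses_per_burst: 40
hz: 30.0
interval_s: 35.0
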