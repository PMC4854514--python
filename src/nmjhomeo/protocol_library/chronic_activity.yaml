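name: chronic_activity
description: >
  Chronic suprathreshold nerve-burst stimulation of a synapse at the set
  point; both calcium signals are engaged and the synaptic gain stays at
  unity with no net plasticity.
drive: nerve
n_bursts: 15
pulses_per_burst: 40
hz: 30.0
interval_s: 40.0
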