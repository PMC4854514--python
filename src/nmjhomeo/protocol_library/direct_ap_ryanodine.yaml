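name: direct_ap_ryanodine
description: >
  Direct muscle APs with ryanodine blocking the sarcoplasmic release: no
  DICR signal, no depression.
drive: muscle
n_bursts: 3
pulses_per_burst: 5
hz: 30.0
interval_s: 30.0
ryanodine: true
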