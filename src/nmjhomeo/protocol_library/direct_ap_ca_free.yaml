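name: direct_ap_ca_free
description: >
  Direct muscle APs in Ca2+-free medium: DICR is independent of external
  calcium, so depression is unchanged.
drive: muscle
n_bursts: 3
pulses_per_burst: 5
hz: 30.0
interval_s: 30.0
ca_free: true
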