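name: curare_subthreshold
description: >
  Synaptic events kept subthreshold with a strong reversible nicotinic
  block during three short bursts; nicotinic calcium without muscle spikes
  drives long-term potentiation.  Test responses are measured after washout.
drive: nerve
n_bursts: 3
pulses_per_burst: 5
hz: 30.0
interval_s: 30.0
curare_factor: 0.05
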