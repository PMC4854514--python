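# nmjhomeo

Homeostatic plasticity of the vertebrate neuromuscular junction, as a
simulator plus analysis toolbox.

Every skeletal muscle fiber is driven by a single motor neuron, and a single
nerve spike reliably fires the fiber — a synaptic gain of one — even though
fibers differ enormously in size and input conductance, and keep changing
with growth and exercise. `nmjhomeo` implements a mechanistic account of how
the synapse stays matched to its target: the muscle cell senses synaptic
activity through two calcium signals — a slow Ca2+ build-up through the
nicotinic receptor channels (reporting synaptic events, weighted by the Ca2+
driving force) and fast depolarisation-induced Ca2+ release from the
sarcoplasmic reticulum, DICR (reporting muscle action potentials) — and
these drive opposing retrograde adjustments of presynaptic acetylcholine
release R:

```
d ln R  =  k_pot · S_nico  −  k_dep · S_dicr        (per conditioning burst)
```

Subthreshold synaptic events potentiate (no spikes, no DICR); muscle spikes
depress; the two balance at a single value of the synaptic-to-input
conductance ratio, Gsyn/Gin ≈ 2.36, which acts as an attractor: synapses
below it strengthen, synapses above it weaken, and a heterogeneous
population converges onto the set point with shrinking spread. The package
contains:

- a conductance-based muscle-cell model (passive leak + inward-rectifier K+
  with first-order gating + threshold-triggered stereotyped action
  potential), with current injection, dynamic-clamp conductances and
  voltage clamp (`nmjhomeo.membrane`);
- the two calcium sensors with their pharmacological switches — ryanodine
  kills DICR, Ca2+-free medium kills the nicotinic influx
  (`nmjhomeo.sensors`);
- the push–pull rule, its deterministic calibration, and the closed-loop
  runner (`nmjhomeo.plasticity`);
- a YAML protocol library replaying the classical conditioning experiments
  (chronic bursts, curare, dynamic clamp, ryanodine, direct muscle
  stimulation, Ca2+-free external stimulation, force drop/recovery under
  curare) over single fibers or populations (`nmjhomeo.protocols`);
- analysis formulas: synaptic gain, Gsyn/Gin from ePSP peaks
  ((−80 − Vp)/Vp), the homeostatic relation
  `after/before = 1 − 1/(1 + s/(x − s)) = s/x`, set-point fitting, sPSC
  frequency/amplitude statistics (`nmjhomeo.analysis`);
- extended Goldman–Hodgkin–Katz reversal potentials for the multi-ion
  nicotinic channel and least-squares recovery of the permeability ratios
  PK/PNa, PCa/PNa, PMg/PNa (`nmjhomeo.ghk`);
- synthetic-data generators for cell populations (conductance density
  196 pS/pF), spontaneous-event trains and before/after ratio datasets
  (`nmjhomeo.synth`).

See `docs/methods.md` for the model equations, parameter choices and
limitations.

## Worked example

Run the ryanodine conditioning experiment — suprathreshold synaptic bursts
with the depression arm silenced — on the reference fiber:

```python
from nmjhomeo.protocols import run_protocol

rec = run_protocol("ryanodine", seed=1)
print(f"Gsyn/Gin before: {rec.ratio_before[0]:.3f}")
print(f"Gsyn/Gin after:  {rec.ratio_after[0]:.3f}")
print(f"spikes per burst: {rec.spikes_per_burst[0]}")
```

```
Gsyn/Gin before: 2.364
Gsyn/Gin after:  4.024
spikes per burst: [5. 5. 5.]
```

The synapse starts at the set point (2.36). Every stimulus fires the muscle
(5 spikes per 5-pulse burst), but with ryanodine the spikes produce no DICR,
so the nicotinic signal potentiates unopposed and the ratio climbs past the
set point (×1.70 after three bursts) instead of holding — the signature of a
broken homeostat. Without ryanodine the same stimulation leaves the ratio
within a few percent of 2.36.

The same machinery runs population experiments:

```python
from nmjhomeo.protocols import run_population
from nmjhomeo.synth import PopulationSpec, generate_cell_population

pop = generate_cell_population(PopulationSpec(n_cells=30), seed=11)
rec = run_population("chronic_convergence", pop, seed=2)
print(f"before: {rec.ratio_before.mean():.2f} ± {rec.ratio_before.std(ddof=1):.2f}")
print(f"after:  {rec.ratio_after.mean():.2f} ± {rec.ratio_after.std(ddof=1):.2f}")
```

```
before: 2.43 ± 0.54
after:  2.35 ± 0.15
```

Twenty-plus minutes of chronic nerve bursts pull every fiber's ratio onto
the set point: the mean lands on 2.36 and the population spread contracts
~3.7-fold.

A command-line interface wraps the same functionality:

```bash
nmjhomeo protocol run --name chronic_activity --seed 1
nmjhomeo generate population --n 19 --seed 2
nmjhomeo ghk fit --measurements measurements.csv
nmjhomeo analyze setpoint --pairs pairs.csv
```

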