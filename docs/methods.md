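# Methods

`nmjhomeo` models how a vertebrate neuromuscular junction keeps its synaptic
strength matched to the excitability of the muscle fiber it innervates. The
observable under regulation is the ratio between the peak evoked synaptic
conductance and the fiber's resting input conductance, Gsyn/Gin; the package
simulates the postsynaptic calcium signals that report synaptic activity,
the retrograde rule that converts them into changes of presynaptic release,
and the measurements used to quantify the resulting homeostasis.

## Membrane model

A muscle fiber is a single compartment with capacitance C and three
conductances (units: mV, nS, pA, pF, ms):

```
C dV/dt = -gleak (V - Eleak) - gmax m (V - EK) - gsyn(t) (V - Esyn) + I(t)
dm/dt   = (m_inf(V) - m) / tau_m,   m_inf(V) = 1 / (1 + exp(-0.074 (EK - V)))
```

- Passive K+ leak: `Eleak = -80 mV`.
- Inward-rectifier K+ (Kir): first-order gate with slope 0.074 /mV and
  `tau_m = 0.2 ms`; the gate closes on depolarisation, so the input
  conductance `Gin(V) = gleak + gmax·m_inf(V)` falls with depolarisation
  and equals `gleak + gmax/2` at the matched rest `V = EK = -80 mV`.
- Nicotinic synapse: difference-of-exponentials conductance (rise 0.3 ms,
  decay 3 ms, unit peak) scaled by the evoked peak conductance
  `Gsyn = R·n_quanta·q·c` (release scale R, quantal conductance q, curare
  block factor c), reversal `Esyn = 0 mV`.
- Reference cell: total conductance density 196 pS/pF, split 1:3 between
  leak and Kir at rest; default C = 100 pF gives Gin = 19.6 nS and a
  membrane time constant of ~5 ms.

The muscle action potential is a threshold device, not a Na+/K+ channel
model: when V crosses -63 mV from below outside the refractory period, the
voltage is forced along a stereotyped piecewise-linear waveform (to +30 mV
in 1 ms, back down in 2 ms) and the spike time is recorded. Downstream
physiology needs only the threshold crossing and a suprathreshold voltage
excursion to drive calcium release. The refractory period is 15 ms: long
enough that one synaptic event (conductance decay 3 ms) can trigger at most
one spike, short enough to follow every stimulus of a 30 Hz burst. A
shorter refractory lets a strong synaptic event re-fire the cell on its
conductance tail, which makes the spike count per event a ragged function
of synaptic strength and fragments the plasticity drive curve.

Integration is forward Euler for V and exact exponential update for the
gates (fastest time constant 0.2 ms). Default dt is 0.02 ms for single
traces and 0.05 ms inside the protocol runner; halving dt moves
subthreshold traces by < 0.1 mV. The integrator is vectorised over a fiber
batch, so population protocols cost the same wall time as one fiber.

## Calcium sensors

Two postsynaptic calcium signals report activity (arbitrary fluorescence
units; only signs, ratios and orderings are meaningful):

**DICR (spike reporter).** Depolarisation-induced Ca2+ release from the
sarcoplasmic reticulum: flux `amplitude · a(V)` with `a(V) = 0` for
V <= -40 mV and a high-voltage-activated Boltzmann
`1/(1 + exp((v_half - V)/v_slope))` above it (v_half = -15 mV, v_slope =
7 mV — typical HVA values, the source data give no fit), decaying with
tau = 50 ms. It is independent of external Ca2+, abolished by ryanodine,
and in practice fires once per muscle action potential — an all-or-none
spike detector whose output also grows smoothly when the post-spike
depolarised tail of a very strong synapse holds V above -40 mV.

**Nicotinic Ca2+ build-up (synaptic-event reporter).** Ca2+ entering
through open nicotinic receptor channels:

```
flux = flux_gain · (PCa/PNa) · gsyn(t)/(gpeak + g_sat) · max(0, Eca - V)
```

with PCa/PNa = 0.23, effective Ca driving-force reversal Eca = +120 mV,
and slow decay tau = 4 s (no transients). The term
`gsyn/(gpeak + g_sat)` is receptor-pool saturation: a strong evoked event
saturates the finite endplate receptor field, so for `gpeak >> g_sat` the
flux follows the *time course* of receptor activation and the driving
force, while for weak inputs (`gpeak << g_sat`, the iontophoresis regime)
it is linear in conductance. The saturation scale g_sat is proportional to
the fiber's resting input conductance (the receptor pool grows with
endplate and fiber size; 1 nS for the 19.6 nS reference cell), which makes
the sensor output invariant to fiber size at fixed Gsyn/Gin. The signal
vanishes in Ca2+-free medium and shrinks with depolarisation through the
driving-force term.

With the defaults, the DICR transient per spike is >= 5x the nicotinic
build-up per event: the fast/large vs slow/small dichotomy that lets the
two signals be read out separately.

## The push-pull rule and its set point

Per conditioning epoch (one burst), the integrated fluxes S_nico and
S_dicr update release multiplicatively:

```
d ln R = clip(k_pot S_nico - k_dep S_dicr, +/- 0.5),   R in [0.05, 20]
```

The step cap models a finite retrograde-signalling capacity per epoch and
prevents a single long burst from catapulting a far-from-equilibrium
synapse across the set point.

Why this has a stable fixed point in Gsyn/Gin: below firing threshold
(Gsyn/Gin below ~0.5 for the reference cell) there is no DICR and every
synaptic event potentiates. Above threshold each stimulus yields exactly
one spike, so S_dicr per event is constant, while S_nico per event *falls*
as the synapse strengthens — a stronger synapse fires the muscle earlier in
the conductance transient, so more of the receptor-open time is spent at
depolarised potentials where the Ca2+ driving force is small. At very high
ratios the post-spike depolarised tail additionally extends DICR. The net
drive is therefore positive below, negative above, and crosses zero with
negative slope at a single ratio.

Calibration (`calibrate_rule`, deterministic, cached): k_pot is set from
the speed of subthreshold potentiation (three 5-pulse 30 Hz bursts under
strong curare must raise R at least 1.5-fold; a 1.2 margin is applied),
then k_dep solves `k_pot S_nico = k_dep S_dicr` for the default burst at
Gsyn/Gin = 2.36, the empirically observed attractor. `find_drive_zero`
verifies by bisection that the calibrated zero crossing sits at the set
point (2.3602). Because the sensors are scale-invariant, one calibrated
rule serves fibers of any size.

## Protocols and measurements

Protocols are declarative YAML configs (burst structure, drive target,
toggles). Conventions: direct muscle drive releases no transmitter; evoked
release requires external Ca2+ (external stimulation in Ca2+-free medium =
spikes without synaptic events); ryanodine silences DICR only. Gsyn is
measured as the average of 35 voltage-clamp test responses with 5%
multiplicative measurement noise, with plasticity frozen; Gin is the
resting input conductance. Chronic schedules are scaled to desk size:
stability runs use 15 bursts of 40 pulses at 30 Hz; convergence runs use
40 bursts of 60 events at 30 Hz every 35 s (~23 min of virtual time).

The contraction-force proxy counts recruited fibers — those firing one
spike per stimulus of a 2 s, 30 Hz tetanic test burst — relative to the
drug-free baseline. The curare dose-to-block table ({0.1 uM: 0.25,
0.5: 0.08, 2: 0.02}, log-interpolated) is a calibration, not a binding
model; the lowest dose is chosen to de-recruit part of the reference
population so that the drop-and-recovery dynamics are visible.

Spontaneous release (Poisson, ~0.15 Hz at R = 1) is generated and analysed
(frequency indexes release, quantal amplitude indexes postsynaptic
sensitivity) but excluded from the plasticity drive: it is two orders of
magnitude sparser than evoked activity.

## GHK permeability module

Reversal potentials of the nicotinic channel follow an extended GHK voltage
equation with fixed activity coefficients (0.75 monovalent, 0.25 divalent)
and a 4x divalent weight, applied symmetrically on both membrane sides
(the internal standard medium has no Ca2+, so the symmetric and asymmetric
conventions coincide on the shipped data). Permeability ratios are fitted
by least squares in log-ratio space from a fixed unit initial guess; a
rank-deficient design triggers an identifiability warning. The shipped
six-media design is synthetic (the original media table is not available
in the source text): external Na+, K+, Ca2+ and Mg2+ are each varied
against the standard pipette medium, which makes all three ratios jointly
identifiable. Defaults are PK/PNa = 1.07, PCa/PNa = 0.23, PMg/PNa = 0.31
at 293.15 K.

## Set-point estimation

Under perfect homeostasis the after-ratio equals the set point s for every
synapse, so the relative change obeys `after/before = s/x` — the same
curve as `1 - 1/(1 + s/(x - s))` written without its removable singularity
at x = s. `fit_set_point` fits s by least squares on log-residuals
(conductance-ratio noise is multiplicative, so log-residuals are
homoscedastic; a raw-scale fit would let the smallest before-ratios
dominate), or reads the mean after-ratio (`mode="mean"`). On noiseless
data both are exact; with 10% noise and n = 40 the fit's standard error is
about 0.04.

## What the synthetic data do and do not emulate

The generators reproduce the population statistics the analyses consume:
capacitance range 100-1000 pF with homogeneous conductance density
(196 pS/pF, 7% scatter), synaptic strength proportional to input
conductance (lognormal scatter, CV 0.25), Poisson spontaneous events with
lognormal amplitudes, multiplicative measurement noise on evoked
responses. They do not emulate cable attenuation between recording site
and endplate (real apparent ratios are underestimates), dye or imaging
noise, channel stochasticity, T-tubule geometry, or contraction mechanics
beyond binary recruitment — so passing tests demonstrate the internal
consistency of the model and its analyses, not fidelity to raw recordings.

## Numerical choices and limitations

- Forward Euler + exponential gating; dt 0.02-0.05 ms; non-finite state
  aborts with a diagnostic; coarse dt (> tau_m/2) warns.
- The Kir gate keeps ~22% steady-state activation at the -63 mV spike
  threshold with the printed slope; measurements suggest the real Kir is
  fully shut there. The printed activation curve is used verbatim; the
  discrepancy only shifts Gin(V) between rest and threshold.
- DICR activation is exactly zero at and below -40 mV by construction
  (strict threshold), making the voltage-step boundary sharp.
- The calibrated drive slope through the set point is shallow (~2% per
  unit ratio for the default burst), so convergence to within 5% of the
  set point needs tens of chronic bursts — matching the tens-of-minutes
  experimental timescale.
- Absolute calcium units are arbitrary; any contract involving the sensors
  uses ratios, signs or orderings only.
- Mono-innervation is assumed throughout; competition between inputs and
  heterosynaptic effects are out of scope.
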