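"""Declarative virtual-experiment protocols and the population runner.

Each protocol replays one of the classical conditioning manipulations at the
neuromuscular synapse as a config object: burst structure (pulses per burst,
intra-burst frequency, inter-burst interval, number of bursts), the drive
target (presynaptic nerve, direct muscle current steps, or external
stimulation of both), and the pharmacological / dynamic-clamp toggles
(curare block factor, added leak/Kir conductances, ryanodine, Ca2+-free
medium).  A library of named protocols ships as YAML files.

Conventions encoded here:

* direct muscle drive releases no transmitter (no nicotinic signal);
* evoked release requires external Ca2+, so under external (nerve + muscle)
  stimulation in Ca2+-free medium the muscle still spikes but the synapse is
  silent — the pure-DICR depression condition;
* Gsyn/Gin is measured from averaged test responses under brief
  voltage-clamp periods with plasticity frozen;
* the contraction-force proxy counts recruited fibers (those firing one
  action potential per stimulus of a test burst), relative to the drug-free
  baseline.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import yaml

from .membrane import KirModel, MuscleCell
from .plasticity import (
    BurstSchedule,
    ExperimentRecord,
    PlasticityRule,
    Synapse,
    calibrate_rule,
    default_cell,
    default_synapse,
    run_closed_loop,
    simulate_burst,
)
from .sensors import DICRSensor, NicotinicCaSensor

__all__ = [
    "ProtocolSpec",
    "load_protocol",
    "list_protocols",
    "run_protocol",
    "run_population",
    "contraction_force",
    "measure_force",
    "run_force_recovery",
    "curare_dose_to_factor",
    "CURARE_DOSE_FACTORS",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """One named virtual experiment."""

    name: str
    drive: str = "nerve"  # nerve | muscle | external | none
    n_bursts: int = 3
    pulses_per_burst: int = 5
    hz: float = 30.0
    interval_s: float = 30.0
    curare_factor: float = 1.0
    curare_during_test: bool = False
    ryanodine: bool = False
    ca_free: bool = False
    dc_gleak: float = 0.0  # nS, dynamic-clamp added passive leak
    dc_gkir: float = 0.0  # nS, dynamic-clamp added Kir gmax
    spike_block: bool = False  # mu-conotoxin: muscle APs disabled
    dt: float = 0.05  # ms
    tail_ms: float = 60.0
    n_test_pulses: int = 35
    test_noise_sd: float = 0.05
    description: str = ""

    def __post_init__(self) -> None:
        if self.drive not in ("nerve", "muscle", "external", "none"):
            raise ValueError(f"unknown drive {self.drive!r}")
        if not 0 <= self.curare_factor <= 1:
            raise ValueError("curare_factor must be in [0, 1]")
        if self.hz <= 0 or self.n_bursts < 0 or self.pulses_per_burst < 1:
            raise ValueError("invalid burst structure")
        if self.drive == "muscle" and self.curare_factor < 1:
            raise ValueError(
                "inconsistent toggles: direct muscle drive involves no transmitter "
                "release, so a curare block factor is meaningless"
            )
        if self.drive == "nerve" and self.ca_free:
            raise ValueError(
                "inconsistent toggles: nerve stimulation in Ca2+-free medium releases "
                "nothing; use drive='external' for the Ca-free depression condition"
            )

    def schedule(self) -> BurstSchedule:
        return BurstSchedule(
            n_bursts=self.n_bursts,
            pulses_per_burst=self.pulses_per_burst,
            hz=self.hz,
            interval_s=self.interval_s,
            drive=self.drive,
            dt=self.dt,
            tail_ms=self.tail_ms,
        )


def list_protocols() -> list[str]:
    """Names of the shipped protocol library."""
    root = importlib.resources.files("nmjhomeo") / "protocol_library"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_protocol(name: str, **overrides) -> ProtocolSpec:
    """Load a named protocol from the shipped YAML library, with overrides."""
    root = importlib.resources.files("nmjhomeo") / "protocol_library"
    path = root / f"{name}.yaml"
    try:
        raw = yaml.safe_load(path.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown protocol {name!r}; available: {list_protocols()}") from None
    raw.update(overrides)
    return ProtocolSpec(**raw)


def _apply_toggles(cell: MuscleCell, spec: ProtocolSpec) -> MuscleCell:
    cell = replace(
        cell,
        ryanodine_blocked=spec.ryanodine,
        external_Ca_present=not spec.ca_free,
    )
    if spec.spike_block:
        cell = replace(cell, spike=replace(cell.spike, enabled=False))
    return cell


def run_protocol(
    spec: ProtocolSpec | str,
    cell: MuscleCell | None = None,
    synapse: Synapse | None = None,
    rule: PlasticityRule | None = None,
    seed: int = 0,
    nico: NicotinicCaSensor | None = None,
    dicr: DICRSensor | None = None,
) -> ExperimentRecord:
    """Run a named or explicit protocol on a single fiber.

    Defaults: the reference cell with its synapse at the set point, and the
    package-calibrated plasticity rule.  Deterministic given (spec, seed).
    """
    if isinstance(spec, str):
        spec = load_protocol(spec)
    nico = nico or NicotinicCaSensor()
    dicr = dicr or DICRSensor()
    base_cell = cell or default_cell()
    # the calibrated rule is scale-invariant, so the reference calibration
    # serves any fiber (and single-fiber runs match population runs exactly)
    rule = rule or calibrate_rule(nico=nico, dicr=dicr)
    syn = synapse or default_synapse(base_cell)
    syn = replace(syn, curare_factor=spec.curare_factor)
    sim_cell = _apply_toggles(base_cell, spec)
    dc_kir = KirModel(gmax=spec.dc_gkir) if spec.dc_gkir > 0 else None
    return run_closed_loop(
        sim_cell,
        syn,
        rule,
        spec.schedule(),
        seed=seed,
        nico=nico,
        dicr=dicr,
        dc_gleak=spec.dc_gleak,
        dc_kir=dc_kir,
        protocol_name=spec.name,
        measure_with_curare=spec.curare_during_test,
        measurement_noise_sd=spec.test_noise_sd,
    )


def run_population(
    spec: ProtocolSpec | str,
    population: Sequence[tuple[MuscleCell, Synapse]],
    rule: PlasticityRule | None = None,
    seed: int = 0,
    nico: NicotinicCaSensor | None = None,
    dicr: DICRSensor | None = None,
) -> ExperimentRecord:
    """Run one protocol over a fiber population (batched, shared schedule).

    The calibrated rule transfers across fiber sizes because the sensor
    drives are scale-invariant: synaptic and input conductance both grow
    with membrane area, so the voltage trajectory — and with it both
    calcium signals — depends on the Gsyn/Gin ratio, not on absolute size.
    """
    if isinstance(spec, str):
        spec = load_protocol(spec)
    nico = nico or NicotinicCaSensor()
    dicr = dicr or DICRSensor()
    cells = [_apply_toggles(c, spec) for c, _ in population]
    syns = [replace(s, curare_factor=spec.curare_factor) for _, s in population]
    rule = rule or calibrate_rule(nico=nico, dicr=dicr)
    dc_kir = KirModel(gmax=spec.dc_gkir) if spec.dc_gkir > 0 else None
    return run_closed_loop(
        cells,
        syns,
        rule,
        spec.schedule(),
        seed=seed,
        nico=nico,
        dicr=dicr,
        dc_gleak=spec.dc_gleak,
        dc_kir=dc_kir,
        protocol_name=spec.name,
        measure_with_curare=spec.curare_during_test,
        measurement_noise_sd=spec.test_noise_sd,
    )


# ---------------------------------------------------------------------------
# contraction-force proxy

#: Calibration table mapping curare bath concentration (uM) to the
#: multiplicative conductance block factor c.  A binding model is not used;
#: the entries are chosen so that the lowest dose pushes part of the
#: reference population below firing threshold.
CURARE_DOSE_FACTORS: dict[float, float] = {0.1: 0.25, 0.5: 0.08, 2.0: 0.02}


def curare_dose_to_factor(dose_um: float) -> float:
    """Block factor for a tabulated curare dose (log-interpolated between entries)."""
    if dose_um == 0:
        return 1.0
    doses = np.array(sorted(CURARE_DOSE_FACTORS))
    if dose_um in CURARE_DOSE_FACTORS:
        return CURARE_DOSE_FACTORS[dose_um]
    if dose_um < doses[0] or dose_um > doses[-1]:
        raise ValueError(f"curare dose {dose_um} uM outside calibrated range {doses[0]}-{doses[-1]}")
    factors = np.array([CURARE_DOSE_FACTORS[d] for d in doses])
    return float(np.exp(np.interp(np.log(dose_um), np.log(doses), np.log(factors))))


def contraction_force(spikes_per_fiber: np.ndarray, n_stimuli: int, unit_force: float = 1.0) -> float:
    """Force produced by a test burst: unit force per recruited fiber.

    A fiber is recruited when it fires at least one action potential per
    stimulus of the burst.  Force is the sum of recruited unit forces —
    monotone in the number of recruited fibers.
    """
    if n_stimuli < 1:
        raise ValueError("need at least one stimulus")
    spikes = np.asarray(spikes_per_fiber, dtype=float)
    return float(unit_force * np.sum(spikes >= n_stimuli))


def measure_force(
    cells: Sequence[MuscleCell],
    synapses: Sequence[Synapse],
    hz: float = 30.0,
    duration_s: float = 2.0,
    dt: float = 0.05,
) -> float:
    """Absolute force (recruited-fiber count) during a 2 s tetanic test burst."""
    n_pulses = int(round(duration_s * hz))
    schedule = BurstSchedule(n_bursts=1, pulses_per_burst=n_pulses, hz=hz, drive="nerve", dt=dt)
    amplitudes = np.array(
        [s.evoked_peak_conductance if c.external_Ca_present else 0.0 for c, s in zip(cells, synapses)]
    )
    result, _, _ = simulate_burst(cells, amplitudes, schedule)
    spikes = np.array([len(s) for s in result.spikes])
    return contraction_force(spikes, n_pulses)


def run_force_recovery(
    population: Sequence[tuple[MuscleCell, Synapse]],
    curare_um: float = 0.1,
    n_bursts: int = 40,
    pulses_per_burst: int = 60,
    hz: float = 30.0,
    interval_s: float = 35.0,
    measure_every: int = 5,
    rule: PlasticityRule | None = None,
    seed: int = 0,
) -> dict:
    """Curare force-drop-and-recovery experiment on a muscle (population).

    Measures tetanic force before curare (baseline), right after applying a
    low curare dose, and then repeatedly during chronic nerve-burst
    stimulation while the homeostatic rule upregulates release.  Returns a
    dict with the curare factor and the relative force trajectory
    (baseline-normalised; index 0 is the baseline, index 1 the acute drop).
    """
    cells = [c for c, _ in population]
    syns = [s for _, s in population]
    rule = rule or calibrate_rule()
    factor = curare_dose_to_factor(curare_um)

    baseline = measure_force(cells, syns, hz=hz)
    if baseline == 0:
        raise RuntimeError("no fiber recruited at baseline; population too weak")
    syns_c = [replace(s, curare_factor=factor) for s in syns]
    forces = [1.0, measure_force(cells, syns_c, hz=hz) / baseline]

    schedule = BurstSchedule(
        n_bursts=measure_every, pulses_per_burst=pulses_per_burst, hz=hz,
        interval_s=interval_s, drive="nerve",
    )
    done = 0
    while done < n_bursts:
        rec = run_closed_loop(cells, syns_c, rule, schedule, seed=seed + done, protocol_name="curare_force")
        syns_c = rec.final_synapses
        done += schedule.n_bursts
        forces.append(measure_force(cells, syns_c, hz=hz) / baseline)

    return {
        "curare_um": curare_um,
        "curare_factor": factor,
        "bursts_per_measurement": measure_every,
        "relative_force": np.array(forces),
        "final_release": np.array([s.release_scale for s in syns_c]),
    }
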