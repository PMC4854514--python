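"""Push-pull retrograde plasticity rule and the closed-loop simulator.

The muscle cell integrates two calcium drives over each conditioning burst —
the nicotinic build-up ``S_nico`` (reporting synaptic events, weighted by the
Ca2+ driving force) and the DICR transients ``S_dicr`` (reporting muscle
action potentials) — and a retrograde signal updates presynaptic release
multiplicatively::

    d ln R = k_pot * S_nico - k_dep * S_dicr      (per conditioning epoch)

Potentiation without spikes, depression from spikes, and a stable balance in
between: because a stronger synapse fires the muscle earlier in the synaptic
event, the per-event nicotinic drive falls with synaptic strength while the
per-spike DICR drive is all-or-none (and grows slightly with strength via the
post-spike depolarised tail).  The net drive as a function of the
synaptic-to-input conductance ratio Gsyn/Gin is therefore positive below a
set point, negative above it, and crosses zero with negative slope — an
attractor.  ``calibrate_rule`` places that zero crossing at the observed set
point (Gsyn/Gin = 2.36) by choosing k_pot from the speed of subthreshold
potentiation and solving k_dep from drive balance at the set point.

Release is presynaptic: the evoked conductance scales with the release scale
R while the quantal (spontaneous-event) amplitude does not; spontaneous event
frequency scales with R.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np

from .membrane import (
    Drive,
    MuscleCell,
    input_conductance,
    resting_potential,
    simulate_batch,
    syn_waveform,
)
from .sensors import DICRSensor, NicotinicCaSensor, batch_sensor_integrals

__all__ = [
    "Synapse",
    "PlasticityRule",
    "HomeostasisParams",
    "BurstSchedule",
    "ExperimentRecord",
    "update_release",
    "run_closed_loop",
    "calibrate_rule",
    "find_drive_zero",
    "drive_curve",
    "default_cell",
    "default_synapse",
]


@dataclass(frozen=True)
class Synapse:
    """Presynaptic release model of one neuromuscular synapse.

    Evoked peak conductance Gsyn = R * n_quanta * q * c where R is the
    (plastic) release scale, q the quantal conductance and c the curare
    block factor.  Spontaneous events have amplitude q*c (independent of R)
    and rate spont_rate * R.
    """

    release_scale: float = 1.0
    quantal_conductance: float = 1.0  # nS
    n_quanta: int = 100
    curare_factor: float = 1.0
    spont_rate: float = 0.15  # Hz, spontaneous release rate at R = 1
    tau_rise: float = 0.3  # ms, synaptic conductance kinetics
    tau_decay: float = 3.0  # ms

    def __post_init__(self) -> None:
        if self.release_scale <= 0:
            raise ValueError("release_scale must be > 0")
        if not 0 <= self.curare_factor <= 1:
            raise ValueError("curare_factor must be in [0, 1]")
        if self.quantal_conductance <= 0 or self.n_quanta <= 0:
            raise ValueError("quantal_conductance and n_quanta must be > 0")

    @property
    def evoked_peak_conductance(self) -> float:
        """Gsyn, nS: peak conductance of one evoked synaptic event."""
        return self.release_scale * self.n_quanta * self.quantal_conductance * self.curare_factor

    @property
    def spsc_amplitude(self) -> float:
        """Quantal (spontaneous) event conductance, nS — independent of R."""
        return self.quantal_conductance * self.curare_factor

    @property
    def spsc_rate(self) -> float:
        """Spontaneous event rate, Hz — proportional to R."""
        return self.spont_rate * self.release_scale


@dataclass(frozen=True)
class PlasticityRule:
    """Gains and bounds of the multiplicative release update."""

    k_pot: float  # per a.u.*ms of S_nico
    k_dep: float  # per a.u.*ms of S_dicr
    r_min: float = 0.05
    r_max: float = 20.0
    max_step: float = 0.5  # cap on |d ln R| per conditioning epoch

    def __post_init__(self) -> None:
        if self.k_pot <= 0 or self.k_dep < 0:
            raise ValueError("k_pot must be > 0 and k_dep >= 0")
        if not 0 < self.r_min < self.r_max:
            raise ValueError("need 0 < r_min < r_max")
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")


@dataclass(frozen=True)
class HomeostasisParams:
    """Target of the homeostatic process: the Gsyn/Gin attractor."""

    set_point: float = 2.36

    def __post_init__(self) -> None:
        if self.set_point <= 0:
            raise ValueError("set_point must be > 0")


@dataclass(frozen=True)
class BurstSchedule:
    """Conditioning stimulation: n_bursts bursts of pulses at hz, spaced interval_s."""

    n_bursts: int = 3
    pulses_per_burst: int = 5
    hz: float = 30.0
    interval_s: float = 30.0
    drive: str = "nerve"  # nerve | muscle | external | none
    dt: float = 0.05  # ms
    tail_ms: float = 60.0

    def __post_init__(self) -> None:
        if self.hz <= 0:
            raise ValueError("burst frequency must be > 0")
        if self.drive not in ("nerve", "muscle", "external", "none"):
            raise ValueError(f"unknown drive {self.drive!r}")

    @property
    def burst_window_ms(self) -> float:
        return self.pulses_per_burst * 1000.0 / self.hz + self.tail_ms

    @property
    def duration_s(self) -> float:
        return self.n_bursts * self.interval_s


@dataclass
class ExperimentRecord:
    """Outcome of one closed-loop virtual experiment (possibly many fibers)."""

    protocol: str
    seed: int
    n_fibers: int
    ratio_before: np.ndarray  # measured Gsyn/Gin per fiber
    ratio_after: np.ndarray
    release_trajectory: np.ndarray  # (n, n_bursts + 1)
    gain_per_burst: np.ndarray  # (n, n_bursts); NaN when no presynaptic pulses
    spikes_per_burst: np.ndarray  # (n, n_bursts)
    S_nico: np.ndarray  # (n, n_bursts)
    S_dicr: np.ndarray  # (n, n_bursts)
    bounds_hit: np.ndarray  # (n,) bool
    final_synapses: list = field(repr=False, default_factory=list)
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def listify(a):
            return np.asarray(a).tolist()

        return {
            "protocol": self.protocol,
            "seed": self.seed,
            "n_fibers": self.n_fibers,
            "ratio_before": listify(self.ratio_before),
            "ratio_after": listify(self.ratio_after),
            "release_trajectory": listify(self.release_trajectory),
            "gain_per_burst": listify(np.nan_to_num(self.gain_per_burst, nan=-1.0)),
            "spikes_per_burst": listify(self.spikes_per_burst),
            "S_nico": listify(self.S_nico),
            "S_dicr": listify(self.S_dicr),
            "bounds_hit": listify(self.bounds_hit.astype(int)),
            "params": self.params,
        }


def default_cell(capacitance: float = 100.0, density_pS_per_pF: float = 196.0, leak_fraction: float = 0.25) -> MuscleCell:
    """Reference muscle cell: conductance density 196 pS/pF, leak:Kir = 1:3 at rest."""
    from .membrane import KirModel, LeakModel

    g_total = density_pS_per_pF * capacitance * 1e-3  # nS
    gleak = leak_fraction * g_total
    # Kir contributes (1 - leak_fraction) of the resting conductance; at rest
    # (V = EK = -80 mV) the gate sits at m_inf = 0.5, hence gmax = 2x that share.
    gmax = 2.0 * (1.0 - leak_fraction) * g_total
    return MuscleCell(capacitance=capacitance, leak=LeakModel(gleak=gleak), kir=KirModel(gmax=gmax))


def default_synapse(cell: MuscleCell, ratio: float = 2.36, quantal_conductance: float = 1.0, n_quanta: int = 100) -> Synapse:
    """Synapse whose evoked Gsyn sits at ``ratio`` times the cell's resting Gin."""
    gin = input_conductance(cell, resting_potential(cell))
    release = ratio * gin / (n_quanta * quantal_conductance)
    return Synapse(release_scale=release, quantal_conductance=quantal_conductance, n_quanta=n_quanta)


def _rest_gin(cell: MuscleCell) -> float:
    return input_conductance(cell, resting_potential(cell))


@lru_cache(maxsize=1)
def _reference_gin() -> float:
    """Resting input conductance of the reference cell (receptor-pool scale unit)."""
    return _rest_gin(default_cell())


def _g_sat_for(cells: Sequence[MuscleCell], nico: NicotinicCaSensor) -> np.ndarray:
    """Per-fiber receptor-saturation conductance, proportional to fiber size."""
    return np.array([nico.g_sat * _rest_gin(c) / _reference_gin() for c in cells])


def update_release(
    synapse: Synapse,
    rule: PlasticityRule,
    S_nico_integral: float,
    S_dicr_integral: float,
    dt: float = 1.0,
) -> Synapse:
    """One multiplicative release update; R is clipped to [r_min, r_max]."""
    if S_nico_integral < 0 or S_dicr_integral < 0:
        raise ValueError("sensor integrals must be non-negative")
    drive = (rule.k_pot * S_nico_integral - rule.k_dep * S_dicr_integral) * dt
    drive = float(np.clip(drive, -rule.max_step, rule.max_step))
    new_R = float(np.clip(synapse.release_scale * math.exp(drive), rule.r_min, rule.r_max))
    return replace(synapse, release_scale=new_R)


# ---------------------------------------------------------------------------
# burst drive construction


def _pulse_times(schedule: BurstSchedule, offset_ms: float = 5.0) -> np.ndarray:
    return offset_ms + np.arange(schedule.pulses_per_burst) * 1000.0 / schedule.hz


def _burst_shapes(schedule: BurstSchedule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shared unit-amplitude gsyn shape and unit current-step shape for one burst."""
    n_steps = int(round(schedule.burst_window_ms / schedule.dt))
    t = np.arange(n_steps) * schedule.dt
    times = _pulse_times(schedule)
    gshape = np.zeros(n_steps)
    step = np.zeros(n_steps)
    for tk in times:
        gshape += syn_waveform(t - tk)
        step += ((t >= tk) & (t < tk + 3.0)).astype(float)
    return t, gshape, step


def simulate_burst(
    cells: Sequence[MuscleCell],
    amplitudes: np.ndarray,
    schedule: BurstSchedule,
    dc_gleak: float = 0.0,
    dc_kir=None,
):
    """Simulate one conditioning burst for a batch of fibers.

    ``amplitudes`` is the per-fiber evoked peak conductance (nS); for
    muscle/external drive a suprathreshold 3-ms current step is injected at
    each pulse time (amplitude auto-scaled to 2.5x rheobase-to-threshold).
    Returns (BatchResult, gsyn (n, T) or None, n_pulses).
    """
    n = len(cells)
    _, gshape, stepshape = _burst_shapes(schedule)
    gsyn = None
    i_inj = None
    if schedule.drive in ("nerve", "external"):
        gsyn = np.asarray(amplitudes, dtype=float)[:, None] * gshape[None, :]
    if schedule.drive in ("muscle", "external"):
        rest = np.array([resting_potential(c) for c in cells])
        gin = np.array([input_conductance(c, r) for c, r in zip(cells, rest)])
        thr = np.array([c.spike.threshold for c in cells])
        amp = 2.5 * gin * (thr - rest)  # pA
        i_inj = amp[:, None] * stepshape[None, :]
    if schedule.drive == "none":
        gsyn = np.zeros((n, len(gshape)))
    drive = Drive(gsyn=gsyn, i_inj=i_inj, dc_gleak=dc_gleak, dc_kir=dc_kir)
    result = simulate_batch(cells, drive, schedule.burst_window_ms, schedule.dt)
    return result, gsyn, schedule.pulses_per_burst


def measure_ratio(
    cells: Sequence[MuscleCell],
    synapses: Sequence[Synapse],
    rng: np.random.Generator,
    n_test_pulses: int = 35,
    noise_sd: float = 0.05,
    include_curare: bool = False,
) -> np.ndarray:
    """Measured Gsyn/Gin per fiber from averaged voltage-clamp test responses.

    Gsyn is the mean of ``n_test_pulses`` evoked-conductance measurements with
    multiplicative Gaussian measurement noise (the classical 30-40 ePSC
    average); Gin is the resting input conductance.  Plasticity is frozen
    during test periods, so measurement does not perturb the loop.
    """
    out = np.empty(len(cells))
    for i, (cell, syn) in enumerate(zip(cells, synapses)):
        base = syn.release_scale * syn.n_quanta * syn.quantal_conductance
        if include_curare:
            base *= syn.curare_factor
        samples = base * (1.0 + noise_sd * rng.standard_normal(n_test_pulses))
        gin = input_conductance(cell, resting_potential(cell))
        out[i] = samples.mean() / gin
    return out


def run_closed_loop(
    cells: MuscleCell | Sequence[MuscleCell],
    synapses: Synapse | Sequence[Synapse],
    rule: PlasticityRule,
    schedule: BurstSchedule,
    seed: int = 0,
    nico: NicotinicCaSensor | None = None,
    dicr: DICRSensor | None = None,
    dc_gleak: float = 0.0,
    dc_kir=None,
    protocol_name: str = "closed_loop",
    measure_with_curare: bool = False,
    measurement_noise_sd: float = 0.05,
) -> ExperimentRecord:
    """Run the full sense-integrate-update loop over a burst schedule.

    Per burst: simulate the membrane and both calcium sensors, integrate the
    sensor drives, and apply one multiplicative release update.  Gsyn/Gin is
    measured (test pulses, plasticity frozen) before and after the schedule.
    Deterministic for fixed inputs and seed.
    """
    single = isinstance(cells, MuscleCell)
    cell_list = [cells] if single else list(cells)
    syn_list = [synapses] if isinstance(synapses, Synapse) else list(synapses)
    if len(syn_list) != len(cell_list):
        raise ValueError("need one synapse per cell")
    n = len(cell_list)
    nico = nico or NicotinicCaSensor()
    dicr = dicr or DICRSensor()
    rng = np.random.default_rng(seed)

    ryanodine = cell_list[0].ryanodine_blocked
    ca_present = cell_list[0].external_Ca_present
    if any(c.ryanodine_blocked != ryanodine or c.external_Ca_present != ca_present for c in cell_list):
        raise ValueError("all fibers in a batch must share ryanodine / external-Ca state")

    ratio_before = measure_ratio(cell_list, syn_list, rng, noise_sd=measurement_noise_sd, include_curare=measure_with_curare)

    R = np.array([s.release_scale for s in syn_list])
    R_traj = np.empty((n, schedule.n_bursts + 1))
    R_traj[:, 0] = R
    gains = np.full((n, schedule.n_bursts), np.nan)
    spikes = np.zeros((n, schedule.n_bursts))
    S_nico_rec = np.zeros((n, schedule.n_bursts))
    S_dicr_rec = np.zeros((n, schedule.n_bursts))

    quanta = np.array([s.n_quanta * s.quantal_conductance * s.curare_factor for s in syn_list])
    release_possible = ca_present  # evoked ACh release requires external Ca2+
    g_sat_fibers = _g_sat_for(cell_list, nico)

    for b in range(schedule.n_bursts):
        amplitudes = R * quanta if release_possible else np.zeros(n)
        result, gsyn, n_pulses = simulate_burst(cell_list, amplitudes, schedule, dc_gleak=dc_gleak, dc_kir=dc_kir)
        s_nico, s_dicr = batch_sensor_integrals(
            result.V, gsyn, schedule.dt, nico, dicr,
            ryanodine_blocked=ryanodine, external_Ca_present=ca_present,
            g_sat=g_sat_fibers,
        )
        n_spikes = np.array([len(s) for s in result.spikes], dtype=float)
        spikes[:, b] = n_spikes
        if schedule.drive in ("nerve", "external") and release_possible:
            gains[:, b] = n_spikes / n_pulses
        S_nico_rec[:, b] = s_nico
        S_dicr_rec[:, b] = s_dicr
        step = np.clip(rule.k_pot * s_nico - rule.k_dep * s_dicr, -rule.max_step, rule.max_step)
        R = np.clip(R * np.exp(step), rule.r_min, rule.r_max)
        R_traj[:, b + 1] = R

    final = [replace(s, release_scale=float(r)) for s, r in zip(syn_list, R)]
    ratio_after = measure_ratio(cell_list, final, rng, noise_sd=measurement_noise_sd, include_curare=measure_with_curare)
    bounds_hit = (R <= rule.r_min * (1 + 1e-9)) | (R >= rule.r_max * (1 - 1e-9))

    return ExperimentRecord(
        protocol=protocol_name,
        seed=seed,
        n_fibers=n,
        ratio_before=ratio_before,
        ratio_after=ratio_after,
        release_trajectory=R_traj,
        gain_per_burst=gains,
        spikes_per_burst=spikes,
        S_nico=S_nico_rec,
        S_dicr=S_dicr_rec,
        bounds_hit=bounds_hit,
        final_synapses=final,
        params={
            "schedule": schedule.__dict__ | {},
            "k_pot": rule.k_pot,
            "k_dep": rule.k_dep,
            "dc_gleak": dc_gleak,
            "ryanodine": ryanodine,
            "external_Ca": ca_present,
        },
    )


# ---------------------------------------------------------------------------
# calibration


def _single_burst_integrals(
    cell: MuscleCell,
    amplitude: float,
    schedule: BurstSchedule,
    nico: NicotinicCaSensor,
    dicr: DICRSensor,
    ryanodine_blocked: bool = False,
) -> tuple[float, float]:
    result, gsyn, _ = simulate_burst([cell], np.array([amplitude]), schedule)
    s_nico, s_dicr = batch_sensor_integrals(
        result.V, gsyn, schedule.dt, nico, dicr, ryanodine_blocked=ryanodine_blocked,
        g_sat=_g_sat_for([cell], nico),
    )
    return float(s_nico[0]), float(s_dicr[0])


def drive_curve(
    ratios: np.ndarray,
    cell: MuscleCell | None = None,
    rule: PlasticityRule | None = None,
    nico: NicotinicCaSensor | None = None,
    dicr: DICRSensor | None = None,
    schedule: BurstSchedule | None = None,
) -> np.ndarray:
    """Net drive d ln R per burst as a function of the Gsyn/Gin ratio.

    The stability sweep: positive below the set point, zero at it, negative
    above it.  Requires a calibrated ``rule`` (defaults to the package
    calibration).
    """
    cell = cell or default_cell()
    nico = nico or NicotinicCaSensor()
    dicr = dicr or DICRSensor()
    schedule = schedule or BurstSchedule()
    rule = rule or calibrate_rule(cell=cell, nico=nico, dicr=dicr, schedule=schedule)
    gin = input_conductance(cell, resting_potential(cell))
    out = np.empty(len(ratios))
    for i, r in enumerate(np.asarray(ratios, dtype=float)):
        s_n, s_d = _single_burst_integrals(cell, r * gin, schedule, nico, dicr)
        out[i] = rule.k_pot * s_n - rule.k_dep * s_d
    return out


@lru_cache(maxsize=32)
def _calibrate_cached(
    cell: MuscleCell,
    nico: NicotinicCaSensor,
    dicr: DICRSensor,
    schedule: BurstSchedule,
    set_point: float,
    subthreshold_curare: float,
    ltp_fold_target: float,
    r_min: float,
    r_max: float,
) -> PlasticityRule:
    gin = input_conductance(cell, resting_potential(cell))

    # speed: three subthreshold bursts must potentiate by >= ltp_fold_target
    s_sub, s_dicr_sub = _single_burst_integrals(
        cell, set_point * gin * subthreshold_curare, schedule, nico, dicr
    )
    if s_dicr_sub > 0:
        raise RuntimeError(
            "calibration subthreshold burst produced spikes; lower subthreshold_curare"
        )
    k_pot = 1.2 * math.log(ltp_fold_target) / (3.0 * s_sub)

    # balance: zero net drive at the set point
    s_n, s_d = _single_burst_integrals(cell, set_point * gin, schedule, nico, dicr)
    if s_d <= 0:
        raise RuntimeError("calibration burst at the set point produced no spikes")
    k_dep = k_pot * s_n / s_d
    return PlasticityRule(k_pot=k_pot, k_dep=k_dep, r_min=r_min, r_max=r_max)


def calibrate_rule(
    cell: MuscleCell | None = None,
    nico: NicotinicCaSensor | None = None,
    dicr: DICRSensor | None = None,
    schedule: BurstSchedule | None = None,
    set_point: float = 2.36,
    subthreshold_curare: float = 0.05,
    ltp_fold_target: float = 1.5,
    r_min: float = 0.05,
    r_max: float = 20.0,
) -> PlasticityRule:
    """Calibrate (k_pot, k_dep) for the default burst so the drive balances.

    k_pot is set from the subthreshold-potentiation speed requirement (three
    5-pulse 30 Hz bursts under strong curare give >= ``ltp_fold_target``-fold
    release increase, with a 20% margin); k_dep then solves
    ``k_pot * S_nico = k_dep * S_dicr`` at Gsyn/Gin = ``set_point``.
    Deterministic; results are cached per parameter set.
    """
    return _calibrate_cached(
        cell or default_cell(),
        nico or NicotinicCaSensor(),
        dicr or DICRSensor(),
        schedule or BurstSchedule(),
        set_point,
        subthreshold_curare,
        ltp_fold_target,
        r_min,
        r_max,
    )


def find_drive_zero(
    rule: PlasticityRule,
    cell: MuscleCell | None = None,
    nico: NicotinicCaSensor | None = None,
    dicr: DICRSensor | None = None,
    schedule: BurstSchedule | None = None,
    lo: float = 1.0,
    hi: float = 6.0,
    tol: float = 1e-3,
) -> float:
    """Deterministic bisection for the zero crossing of the net drive.

    Used to verify that the calibrated rule has its attractor at the set
    point; raises if the bracket does not straddle a sign change.
    """
    cell = cell or default_cell()
    nico = nico or NicotinicCaSensor()
    dicr = dicr or DICRSensor()
    schedule = schedule or BurstSchedule()
    gin = input_conductance(cell, resting_potential(cell))

    def net(r: float) -> float:
        s_n, s_d = _single_burst_integrals(cell, r * gin, schedule, nico, dicr)
        return rule.k_pot * s_n - rule.k_dep * s_d

    f_lo, f_hi = net(lo), net(hi)
    if not (f_lo > 0 > f_hi):
        raise ValueError(f"net drive does not change sign on [{lo}, {hi}]: {f_lo:.3g}, {f_hi:.3g}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
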