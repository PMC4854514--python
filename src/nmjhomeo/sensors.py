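"""Postsynaptic calcium sensors of the muscle cell.

Two calcium signals report synaptic activity to the plasticity machinery:

* **DICR** (depolarization-induced Ca2+ release): sarcoplasmic-reticulum
  release through ryanodine receptors, gated by a membrane voltage sensor.
  Activation is zero at and below -40 mV and follows a high-voltage-activated
  Boltzmann curve above it, so in practice each muscle action potential
  produces one large, fast transient.  The signal is independent of external
  Ca2+ and abolished by ryanodine.

* **Nicotinic Ca2+ build-up**: slow accumulation of Ca2+ entering through
  open nicotinic receptor-channels (PCa/PNa = 0.23).  The influx is the
  product of receptor activation and the Ca2+ driving force, so it reports
  the occurrence of synaptic events, shrinks with postsynaptic
  depolarisation, and vanishes in Ca2+-free medium.

Receptor-pool saturation
------------------------
The endplate receptor pool is finite, and acetylcholine released by a strong
evoked event saturates it.  The nicotinic flux therefore uses a saturating
conductance term ``gsyn / (gpeak + g_sat)`` where ``gpeak`` is the peak
evoked conductance of the trace: for weak inputs (``gpeak << g_sat``, the
iontophoresis regime) the flux is linear in conductance, while for strong
evoked events the flux follows the *time course* of receptor activation and
the instantaneous driving force.  This is what makes the per-event
potentiating signal shrink as synapses grow — larger synapses fire the
muscle earlier, so more of the receptor-open time is spent at depolarised
potentials with a reduced Ca2+ driving force.

Signals are in arbitrary fluorescence-like units (the underlying recordings
are relative dye fluorescence); all downstream contracts use ratios, signs
and orderings, never absolute calcium concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .membrane import VoltageTrace

__all__ = [
    "DICRSensor",
    "NicotinicCaSensor",
    "SensorState",
    "dicr_activation",
    "dicr_signal",
    "nicotinic_ca_signal",
    "compute_sensor_state",
    "batch_sensor_integrals",
    "dicr_step_response",
]


@dataclass(frozen=True)
class DICRSensor:
    """Voltage-gated sarcoplasmic-reticulum release sensor (HVA-type)."""

    threshold: float = -40.0  # mV, strict: activation(V <= threshold) = 0
    v_half: float = -15.0  # mV
    v_slope: float = 7.0  # mV
    amplitude: float = 1.0  # a.u. flux per ms at full activation
    tau_decay: float = 50.0  # ms

    def __post_init__(self) -> None:
        if self.amplitude <= 0 or self.tau_decay <= 0 or self.v_slope <= 0:
            raise ValueError("amplitude, tau_decay and v_slope must be > 0")


@dataclass(frozen=True)
class NicotinicCaSensor:
    """Slow nicotinic Ca2+ build-up sensor."""

    flux_gain: float = 1.5e-3  # a.u. per nS*ms of saturated flux
    tau_decay: float = 4000.0  # ms, much slower than the DICR transient
    ca_reversal: float = 120.0  # mV, effective Ca2+ driving-force reversal
    g_sat: float = 1.0  # nS, receptor-pool saturation scale
    pca_ratio: float = 0.23  # PCa/PNa of the nicotinic channel

    def __post_init__(self) -> None:
        if self.flux_gain < 0:
            raise ValueError("flux_gain must be >= 0")
        if self.tau_decay <= 0 or self.g_sat <= 0:
            raise ValueError("tau_decay and g_sat must be > 0")


@dataclass
class SensorState:
    """Integrated sensor drives and time-resolved calcium traces for an epoch.

    ``S_nico`` and ``S_dicr`` are the time integrals of the respective influx
    terms over the epoch (a.u.*ms) — the quantities the retrograde plasticity
    rule consumes.  The calcium traces are the low-pass filtered signals a
    fluorescent dye would report.
    """

    S_nico: float
    S_dicr: float
    ca_nico: np.ndarray = field(repr=False)
    ca_dicr: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.S_nico < 0 or self.S_dicr < 0:
            raise ValueError("sensor integrals must be non-negative")


def dicr_activation(V, sensor: DICRSensor | None = None):
    """DICR voltage-sensor activation in [0, 1); exactly 0 for V <= threshold."""
    sensor = sensor or DICRSensor()
    V = np.asarray(V, dtype=float)
    boltz = 1.0 / (1.0 + np.exp((sensor.v_half - V) / sensor.v_slope))
    return np.where(V <= sensor.threshold, 0.0, boltz)


def _ca_filter(flux: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Exact exponential-integrator solution of dCa/dt = flux - Ca/tau."""
    decay = np.exp(-dt / tau)
    return lfilter([tau * (1.0 - decay)], [1.0, -decay], flux)


def dicr_signal(
    trace: VoltageTrace,
    sensor: DICRSensor | None = None,
    ryanodine_blocked: bool = False,
) -> np.ndarray:
    """DICR calcium trace (a.u.) for a voltage trace.

    Identically zero under ryanodine block; independent of external Ca2+
    (sarcoplasmic-reticulum release does not require Ca2+ influx).
    """
    sensor = sensor or DICRSensor()
    if ryanodine_blocked:
        return np.zeros_like(trace.V)
    flux = sensor.amplitude * dicr_activation(trace.V, sensor)
    return _ca_filter(flux, sensor.tau_decay, trace.dt)


def nicotinic_flux(
    V: np.ndarray,
    gsyn: np.ndarray,
    sensor: NicotinicCaSensor,
    external_Ca_present: bool = True,
) -> np.ndarray:
    """Instantaneous nicotinic Ca2+ influx term (a.u./ms)."""
    if not external_Ca_present:
        return np.zeros_like(np.asarray(V, dtype=float))
    gsyn = np.asarray(gsyn, dtype=float)
    gpeak = float(np.max(gsyn)) if gsyn.size else 0.0
    occupancy = gsyn / (gpeak + sensor.g_sat)
    driving_force = np.maximum(0.0, sensor.ca_reversal - np.asarray(V, dtype=float))
    return sensor.flux_gain * sensor.pca_ratio * occupancy * driving_force


def nicotinic_ca_signal(
    trace: VoltageTrace,
    gsyn_waveform: np.ndarray,
    sensor: NicotinicCaSensor | None = None,
    external_Ca_present: bool = True,
) -> np.ndarray:
    """Nicotinic Ca2+ build-up trace (a.u.), aligned with the voltage trace.

    Zero without synaptic conductance and in Ca2+-free medium; at a fixed
    holding potential the steady build-up increases monotonically with the
    conductance amplitude.
    """
    sensor = sensor or NicotinicCaSensor()
    gsyn = np.asarray(gsyn_waveform, dtype=float)
    if gsyn.shape != trace.V.shape:
        raise ValueError("gsyn waveform must be aligned with the voltage trace")
    flux = nicotinic_flux(trace.V, gsyn, sensor, external_Ca_present)
    return _ca_filter(flux, sensor.tau_decay, trace.dt)


def dicr_step_response(
    cell,
    command_mV: float,
    sensor: DICRSensor | None = None,
    hold_mV: float = -80.0,
    step_ms: float = 500.0,
    pre_ms: float = 50.0,
    dt: float = 0.05,
) -> float:
    """Steady-state DICR amplitude for one voltage-clamp step (a.u.).

    The classical step protocol: hold, step to the command potential and read
    the calcium signal at its steady state (mean over the last 10% of the
    step, long after the sensor's decay time constant).
    """
    from .membrane import Drive, simulate_membrane

    sensor = sensor or DICRSensor()
    n = int(round((pre_ms + step_ms) / dt))
    cmd = np.full(n, hold_mV)
    cmd[int(pre_ms / dt):] = command_mV
    trace = simulate_membrane(cell, Drive(v_command=cmd), duration=pre_ms + step_ms, dt=dt)
    ca = dicr_signal(trace, sensor, ryanodine_blocked=cell.ryanodine_blocked)
    tail = int(0.1 * step_ms / dt)
    return float(np.mean(ca[-tail:]))


def batch_sensor_integrals(
    V: np.ndarray,
    gsyn: np.ndarray | None,
    dt: float,
    nico: NicotinicCaSensor | None = None,
    dicr: DICRSensor | None = None,
    ryanodine_blocked: bool = False,
    external_Ca_present: bool = True,
    g_sat: np.ndarray | float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrated (S_nico, S_dicr) drives for a batch of cells, shape (n,).

    Same definitions as :func:`compute_sensor_state`, vectorised over the
    leading axis; the receptor-saturation peak conductance is taken per cell.
    ``g_sat`` overrides the sensor's saturation scale per fiber — the
    receptor pool grows with endplate (fiber) size, so callers simulating
    fibers of different sizes pass a value proportional to each fiber's
    input conductance to keep the drive scale-invariant.
    """
    nico = nico or NicotinicCaSensor()
    dicr = dicr or DICRSensor()
    V = np.atleast_2d(np.asarray(V, dtype=float))
    n = V.shape[0]

    if gsyn is None or not external_Ca_present:
        s_nico = np.zeros(n)
    else:
        if g_sat is None:
            g_sat = nico.g_sat
        g_sat = np.atleast_1d(np.asarray(g_sat, dtype=float))[:, None]
        gsyn = np.atleast_2d(np.asarray(gsyn, dtype=float))
        gpeak = gsyn.max(axis=1, keepdims=True)
        occupancy = gsyn / (gpeak + g_sat)
        driving = np.maximum(0.0, nico.ca_reversal - V)
        s_nico = nico.flux_gain * nico.pca_ratio * np.sum(occupancy * driving, axis=1) * dt

    if ryanodine_blocked:
        s_dicr = np.zeros(n)
    else:
        s_dicr = dicr.amplitude * np.sum(dicr_activation(V, dicr), axis=1) * dt
    return s_nico, s_dicr


def compute_sensor_state(
    trace: VoltageTrace,
    gsyn_waveform: np.ndarray | None,
    nico: NicotinicCaSensor | None = None,
    dicr: DICRSensor | None = None,
    ryanodine_blocked: bool = False,
    external_Ca_present: bool = True,
) -> SensorState:
    """Both calcium signals and their integrated drives for one epoch."""
    nico = nico or NicotinicCaSensor()
    dicr = dicr or DICRSensor()
    if gsyn_waveform is None:
        gsyn_waveform = np.zeros_like(trace.V)
    gsyn = np.asarray(gsyn_waveform, dtype=float)

    flux_nico = nicotinic_flux(trace.V, gsyn, nico, external_Ca_present)
    if ryanodine_blocked:
        flux_dicr = np.zeros_like(trace.V)
    else:
        flux_dicr = dicr.amplitude * dicr_activation(trace.V, dicr)

    return SensorState(
        S_nico=float(np.sum(flux_nico) * trace.dt),
        S_dicr=float(np.sum(flux_dicr) * trace.dt),
        ca_nico=_ca_filter(flux_nico, nico.tau_decay, trace.dt),
        ca_dicr=_ca_filter(flux_dicr, dicr.tau_decay, trace.dt),
    )
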