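"""Muscle-cell membrane dynamics.

A single-compartment conductance model of the (embryonic Xenopus / adult
mouse) skeletal muscle fiber:

* passive K+ leak,  Ileak = gleak * (V - Eleak),
* inward-rectifier K+ (Kir) conductance with first-order gating,
  IKir = gmax * m * (V - EK),  dm/dt = (m_inf - m) / tau_m,
  m_inf(V) = 1 / (1 + exp(-0.074 * (EK - V))),  tau_m = 0.2 ms,
* nicotinic synaptic conductance (reversal 0 mV) given as a waveform,
* injected current steps and dynamic-clamp conductances (leak and/or a Kir
  copy computed online from the simulated voltage), and
* a threshold-triggered stereotyped action potential: when V crosses the
  spike threshold from below (default -63 mV) outside the refractory period,
  the voltage is forced along a piecewise-linear waveform (rise to +30 mV in
  1 ms, fall in 2 ms), and the spike time is recorded.  The muscle AP here is
  an event marker driving downstream calcium signalling, not a Na+/K+ channel
  model.

Integration is forward Euler for the voltage and exact exponential update for
the gating variables (the fastest time constant is tau_m = 0.2 ms; default
dt = 0.02 ms).  All voltages in mV, conductances in nS, currents in pA,
capacitance in pF, time in ms — with these units dV/dt = I/C comes out in
mV/ms directly.

The integrator is natively vectorised over a batch of cells (shape (n,) state
arrays); single-cell simulation is the n = 1 case.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "LeakModel",
    "KirModel",
    "SpikeMechanism",
    "MuscleCell",
    "VoltageTrace",
    "Drive",
    "kir_steady_state",
    "input_conductance",
    "resting_potential",
    "simulate_membrane",
    "simulate_batch",
    "epsp_peak",
    "syn_waveform",
    "SpikeContaminationWarning",
]

E_SYN = 0.0  # mV, nicotinic reversal potential


class SpikeContaminationWarning(UserWarning):
    """A subthreshold measurement window contained an action potential."""


@dataclass(frozen=True)
class LeakModel:
    """Passive K+ leak: gleak in nS, Eleak in mV."""

    gleak: float = 4.9
    Eleak: float = -80.0

    def __post_init__(self) -> None:
        if self.gleak < 0:
            raise ValueError("gleak must be >= 0")


@dataclass(frozen=True)
class KirModel:
    """Inward-rectifier K+ conductance with first-order gating."""

    gmax: float = 29.4  # nS
    EK: float = -80.0  # mV
    slope: float = 0.074  # 1/mV
    tau_m: float = 0.2  # ms

    def __post_init__(self) -> None:
        if self.gmax < 0:
            raise ValueError("gmax must be >= 0")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be > 0")


@dataclass(frozen=True)
class SpikeMechanism:
    """Threshold-triggered stereotyped action potential."""

    threshold: float = -63.0  # mV
    ap_peak: float = 30.0  # mV
    rise_ms: float = 1.0
    fall_ms: float = 2.0
    refractory_ms: float = 15.0
    reset: float = -75.0  # mV, voltage at the end of the falling phase
    enabled: bool = True  # disabled models mu-conotoxin block of muscle Nav

    def __post_init__(self) -> None:
        if self.ap_peak <= self.threshold:
            raise ValueError("ap_peak must exceed threshold")
        if self.rise_ms <= 0 or self.fall_ms <= 0 or self.refractory_ms <= 0:
            raise ValueError("durations must be > 0")

    @property
    def ap_duration(self) -> float:
        return self.rise_ms + self.fall_ms


@dataclass(frozen=True)
class MuscleCell:
    """Postsynaptic muscle cell: capacitance plus leak, Kir and spike models.

    ``ryanodine_blocked`` and ``external_Ca_present`` are experimental
    switches consumed by the calcium-sensor module.
    """

    capacitance: float = 100.0  # pF
    leak: LeakModel = field(default_factory=LeakModel)
    kir: KirModel = field(default_factory=KirModel)
    spike: SpikeMechanism = field(default_factory=SpikeMechanism)
    ryanodine_blocked: bool = False
    external_Ca_present: bool = True

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ValueError("capacitance must be > 0")
        if self.input_conductance(self.leak.Eleak) <= 0:
            raise ValueError("input conductance at rest must be > 0")

    def input_conductance(self, V: float) -> float:
        return input_conductance(self, V)


def kir_steady_state(V, EK: float = -80.0, slope: float = 0.074):
    """Kir steady-state activation m_inf(V) = 1/(1+exp(-slope*(EK-V)))."""
    return 1.0 / (1.0 + np.exp(-slope * (EK - np.asarray(V, dtype=float))))


def input_conductance(cell: MuscleCell, V: float) -> float:
    """Chord input conductance gleak + gmax*m_inf(V), in nS.

    Decreases with depolarisation (the Kir gate closes) and equals the leak
    conductance when gmax = 0.
    """
    return float(cell.leak.gleak + cell.kir.gmax * kir_steady_state(V, cell.kir.EK, cell.kir.slope))


def resting_potential(cell: MuscleCell) -> float:
    """Zero-current resting potential with no drive (solved numerically)."""
    leak, kir = cell.leak, cell.kir

    def net_current(V: float) -> float:
        m = kir_steady_state(V, kir.EK, kir.slope)
        return -(leak.gleak * (V - leak.Eleak) + kir.gmax * m * (V - kir.EK))

    if kir.gmax == 0 or leak.gleak == 0 or leak.Eleak == kir.EK:
        return kir.EK if leak.gleak == 0 and kir.gmax > 0 else leak.Eleak
    lo, hi = sorted((leak.Eleak, kir.EK))
    return float(brentq(net_current, lo, hi))


def syn_waveform(t: np.ndarray, tau_rise: float = 0.3, tau_decay: float = 3.0) -> np.ndarray:
    """Unit-peak difference-of-exponentials conductance waveform (t in ms)."""
    if tau_rise >= tau_decay:
        raise ValueError("tau_rise must be < tau_decay")
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay) - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return raw / peak


@dataclass
class Drive:
    """External drive for a simulation window.

    ``gsyn``/``i_inj`` are per-step waveforms of shape (T,) or (n, T); the
    dynamic-clamp entries are conductance models whose current is computed
    online from the simulated voltage.  ``v_command`` switches the run to
    voltage clamp (V follows the command; no spikes)."""

    gsyn: np.ndarray | None = None  # nS
    i_inj: np.ndarray | None = None  # pA
    dc_gleak: float = 0.0  # nS
    dc_Eleak: float = -80.0  # mV
    dc_kir: KirModel | None = None
    v_command: np.ndarray | None = None  # mV


@dataclass
class VoltageTrace:
    """Uniformly sampled simulation output for one cell."""

    dt: float  # ms
    V: np.ndarray  # mV, shape (T,)
    spike_times: np.ndarray  # ms
    channels: dict = field(default_factory=dict)  # per-step waveforms (gsyn, i_inj, ...)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.V)):
            raise ValueError("voltage trace contains non-finite values")

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.V)) * self.dt

    @property
    def duration(self) -> float:
        return len(self.V) * self.dt

    def to_frame(self):
        import pandas as pd

        data = {"time_ms": self.t, "V_mV": self.V}
        for name, values in self.channels.items():
            data[name] = values
        return pd.DataFrame(data)


class BatchResult:
    """Raw batched integration output: V (n, T), m (n,), spikes per cell."""

    def __init__(self, dt: float, V: np.ndarray, spikes: list[np.ndarray], gsyn: np.ndarray | None):
        self.dt = dt
        self.V = V
        self.spikes = spikes
        self.gsyn = gsyn


def _as_param_array(cells: Sequence[MuscleCell], getter) -> np.ndarray:
    return np.array([getter(c) for c in cells], dtype=float)


def simulate_batch(
    cells: Sequence[MuscleCell],
    drive: Drive,
    duration: float,
    dt: float = 0.02,
) -> BatchResult:
    """Integrate a batch of cells sharing a common time grid.

    All cells see the same drive structure; ``gsyn``/``i_inj`` may be (T,)
    (shared) or (n, T) (per cell).
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = len(cells)
    tau_min = min(c.kir.tau_m for c in cells)
    if dt > tau_min / 2:
        warnings.warn(
            f"dt={dt} ms is coarse for the Kir gating time constant {tau_min} ms; "
            "expect degraded accuracy",
            stacklevel=2,
        )
    n_steps = int(round(duration / dt))

    gleak = _as_param_array(cells, lambda c: c.leak.gleak)
    Eleak = _as_param_array(cells, lambda c: c.leak.Eleak)
    gmax = _as_param_array(cells, lambda c: c.kir.gmax)
    EK = _as_param_array(cells, lambda c: c.kir.EK)
    slope = _as_param_array(cells, lambda c: c.kir.slope)
    tau_m = _as_param_array(cells, lambda c: c.kir.tau_m)
    C = _as_param_array(cells, lambda c: c.capacitance)
    thr = _as_param_array(cells, lambda c: c.spike.threshold)
    peak = _as_param_array(cells, lambda c: c.spike.ap_peak)
    rise = _as_param_array(cells, lambda c: c.spike.rise_ms)
    fall = _as_param_array(cells, lambda c: c.spike.fall_ms)
    refr = _as_param_array(cells, lambda c: c.spike.refractory_ms)
    reset = _as_param_array(cells, lambda c: c.spike.reset)
    spikes_on = np.array([c.spike.enabled for c in cells], dtype=bool)

    def channel(w):
        if w is None:
            return None
        w = np.asarray(w, dtype=float)
        if w.ndim == 1:
            w = np.broadcast_to(w, (n, w.shape[0]))
        if w.shape != (n, n_steps):
            raise ValueError(f"drive waveform shape {w.shape} != {(n, n_steps)}")
        return w

    gsyn = channel(drive.gsyn)
    i_inj = channel(drive.i_inj)
    v_cmd = channel(drive.v_command)

    alpha = 1.0 - np.exp(-dt / tau_m)
    dc_kir = drive.dc_kir
    if dc_kir is not None:
        alpha_dc = 1.0 - np.exp(-dt / dc_kir.tau_m)

    # initial state: resting potential, gating at steady state
    V = np.array([resting_potential(c) for c in cells])
    if v_cmd is not None:
        V = v_cmd[:, 0].copy()
    m = kir_steady_state(V, EK, slope)
    m_dc = kir_steady_state(V, dc_kir.EK, dc_kir.slope) if dc_kir is not None else None

    in_ap = np.zeros(n, dtype=bool)
    ap_start = np.full(n, -np.inf)
    ap_v0 = V.copy()
    refr_until = np.full(n, -np.inf)
    spike_times: list[list[float]] = [[] for _ in range(n)]

    V_out = np.empty((n, n_steps))

    for k in range(n_steps):
        t = k * dt
        if v_cmd is not None:
            V = v_cmd[:, k]
            m = m + (kir_steady_state(V, EK, slope) - m) * alpha
            V_out[:, k] = V
            continue

        # gating (exponential Euler, exact for frozen V)
        m = m + (kir_steady_state(V, EK, slope) - m) * alpha
        I = -gleak * (V - Eleak) - gmax * m * (V - EK)
        if gsyn is not None:
            I = I - gsyn[:, k] * (V - E_SYN)
        if drive.dc_gleak:
            I = I - drive.dc_gleak * (V - drive.dc_Eleak)
        if dc_kir is not None:
            m_dc = m_dc + (kir_steady_state(V, dc_kir.EK, dc_kir.slope) - m_dc) * alpha_dc
            I = I - dc_kir.gmax * m_dc * (V - dc_kir.EK)
        if i_inj is not None:
            I = I + i_inj[:, k]
        V_new = V + dt * I / C

        if not np.all(np.isfinite(V_new)):
            raise FloatingPointError(
                f"non-finite membrane potential at t={t:.3f} ms; reduce dt or check drive amplitudes"
            )

        # spike triggering and stereotyped waveform override
        trigger = spikes_on & ~in_ap & (V_new >= thr) & (V < thr) & (t >= refr_until)
        if np.any(trigger):
            idx = np.nonzero(trigger)[0]
            for i in idx:
                spike_times[i].append(t)
            ap_start[trigger] = t
            ap_v0[trigger] = V[trigger]
            refr_until[trigger] = t + refr[trigger]
            in_ap[trigger] = True

        if np.any(in_ap):
            tt = t - ap_start
            rising = in_ap & (tt < rise)
            falling = in_ap & (tt >= rise) & (tt < rise + fall)
            done = in_ap & (tt >= rise + fall)
            V_new = np.where(rising, ap_v0 + (peak - ap_v0) * tt / np.maximum(rise, 1e-12), V_new)
            V_new = np.where(
                falling,
                peak + (reset - peak) * (tt - rise) / np.maximum(fall, 1e-12),
                V_new,
            )
            if np.any(done):
                V_new = np.where(done, reset, V_new)
                in_ap = in_ap & ~done

        V = V_new
        V_out[:, k] = V

    return BatchResult(dt, V_out, [np.array(s) for s in spike_times], gsyn)


def simulate_membrane(
    cell: MuscleCell,
    drive: Drive,
    duration: float,
    dt: float = 0.02,
) -> VoltageTrace:
    """Simulate one cell; see module docstring for the membrane equation."""
    result = simulate_batch([cell], drive, duration, dt)
    channels = {}
    if result.gsyn is not None:
        channels["gsyn_nS"] = result.gsyn[0]
    if drive.i_inj is not None:
        i = np.asarray(drive.i_inj, dtype=float)
        channels["i_inj_pA"] = i if i.ndim == 1 else i[0]
    return VoltageTrace(
        dt=dt,
        V=result.V[0],
        spike_times=result.spikes[0],
        channels=channels,
        params={"capacitance_pF": cell.capacitance, "gleak_nS": cell.leak.gleak, "gmax_nS": cell.kir.gmax},
    )


def epsp_peak(trace: VoltageTrace, event_time: float, window_ms: float = 20.0) -> float:
    """Peak membrane potential (mV) in a window after a synaptic event.

    Emits :class:`SpikeContaminationWarning` when an action potential falls
    inside the measurement window (the peak then reflects the spike, not the
    subthreshold ePSP).
    """
    if not 0 <= event_time <= trace.duration:
        raise ValueError("event_time outside trace span")
    i0 = int(event_time / trace.dt)
    i1 = min(int((event_time + window_ms) / trace.dt) + 1, len(trace.V))
    if i1 <= i0:
        raise ValueError("empty measurement window")
    if np.any((trace.spike_times >= event_time) & (trace.spike_times <= event_time + window_ms)):
        warnings.warn(
            "action potential inside the ePSP measurement window",
            SpikeContaminationWarning,
            stacklevel=2,
        )
    return float(np.max(trace.V[i0:i1]))
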