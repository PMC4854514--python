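"""Measurement formulas and statistics for neuromuscular homeostasis data.

* synaptic gain — ratio of post- to presynaptic action-potential counts
  (unity gain = faithful relay of the motor command);
* Gsyn/Gin from the ePSP peak under the linear-divider assumption
  (synaptic reversal 0 mV, leak reversal -80 mV);
* the theoretical homeostatic relation between the degree of plasticity and
  the distance of the initial Gsyn/Gin ratio to the attractor set point;
* least-squares set-point estimation from before/after ratio pairs;
* spontaneous-PSC frequency/amplitude statistics (the presynaptic-locus
  diagnostic: release changes move sPSC frequency, not amplitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "HomeostasisDataset",
    "SPSCSample",
    "SetPointFit",
    "synaptic_gain",
    "gsyn_gin_from_epsp_peak",
    "homeostatic_relative_change",
    "fit_set_point",
    "spsc_stats",
]


@dataclass
class HomeostasisDataset:
    """Before/after Gsyn/Gin ratio pairs for a set of synapses."""

    ratio_before: np.ndarray
    ratio_after: np.ndarray
    condition: str = "control"

    def __post_init__(self) -> None:
        self.ratio_before = np.asarray(self.ratio_before, dtype=float)
        self.ratio_after = np.asarray(self.ratio_after, dtype=float)
        if self.ratio_before.shape != self.ratio_after.shape:
            raise ValueError("before/after arrays must have equal length")
        if np.any(self.ratio_before <= 0) or np.any(self.ratio_after <= 0):
            raise ValueError("Gsyn/Gin ratios must be > 0")

    def __len__(self) -> int:
        return len(self.ratio_before)

    @property
    def relative_change(self) -> np.ndarray:
        return self.ratio_after / self.ratio_before


@dataclass
class SPSCSample:
    """Spontaneous postsynaptic current sample: event times (ms) + amplitudes (nS)."""

    times_ms: np.ndarray
    amplitudes: np.ndarray
    duration_ms: float

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times_ms.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must have equal length")
        if np.any(np.diff(self.times_ms) < 0):
            raise ValueError("event times must be sorted")
        if np.any(self.amplitudes <= 0):
            raise ValueError("amplitudes must be > 0")
        if self.duration_ms < 0:
            raise ValueError("duration must be >= 0")

    @property
    def rate_hz(self) -> float:
        if self.duration_ms == 0:
            raise ValueError("empty-duration sample has no rate")
        return 1000.0 * len(self.times_ms) / self.duration_ms


def synaptic_gain(pre_spike_count: int, post_spike_count: int) -> float:
    """Post/pre action-potential count ratio; 1 is a faithful relay."""
    if pre_spike_count <= 0:
        raise ValueError("synaptic gain undefined without presynaptic spikes")
    if post_spike_count < 0:
        raise ValueError("spike counts must be >= 0")
    return post_spike_count / pre_spike_count


def gsyn_gin_from_epsp_peak(vp: float, e_syn: float = 0.0, e_leak: float = -80.0) -> float:
    """Apparent Gsyn/Gin from the ePSP peak potential Vp (linear divider).

    With the default reversals this is (-80 - Vp) / Vp: at the peak of a
    quasi-static ePSP the membrane sits at the conductance-weighted mean of
    the leak and synaptic reversal potentials.  Valid for Vp strictly between
    the two reversals; an apparent, distance-attenuated estimate in real
    fiber recordings.
    """
    if not (min(e_leak, e_syn) < vp < max(e_leak, e_syn)):
        raise ValueError(f"ePSP peak {vp} mV outside ({e_leak}, {e_syn}) mV")
    return (vp - e_leak) / (e_syn - vp)


def homeostatic_relative_change(ratio_before, set_point: float):
    """Theoretical relative change in Gsyn/Gin under perfect homeostasis.

    The canonical form 1 - 1/(1 + s/(x - s)) is singular at x = s; it is
    algebraically equal to s/x everywhere else and its continuity limit at
    x = s is 1 (no change at the set point), so the identity s/x is used.
    """
    x = np.asarray(ratio_before, dtype=float)
    if np.any(x <= 0) or set_point <= 0:
        raise ValueError("ratios and set point must be > 0")
    out = set_point / x
    return float(out) if np.isscalar(ratio_before) else out


class SetPointFit(NamedTuple):
    """Set-point estimate with its standard error and fit residuals."""

    set_point: float
    se: float
    residuals: np.ndarray


def fit_set_point(dataset: HomeostasisDataset, mode: str = "fit") -> SetPointFit:
    """Estimate the homeostatic set point from before/after ratio pairs.

    mode="fit": least-squares fit of the relative change after/before against
    the theoretical homeostatic relation (response s/x) over the set point s.
    Residuals are taken on the log scale: measurement error in conductance
    ratios is multiplicative, so log-residuals are the homoscedastic choice
    (and the estimate is then also invariant to which side of the ratio is
    noisy).  mode="mean": the mean after-ratio (how a set point is read off
    a converged population).  On noiseless perfectly homeostatic data both
    recover the generating value exactly.
    """
    if len(dataset) < 3:
        raise ValueError("need at least 3 synapses to estimate a set point")
    x = dataset.ratio_before
    y = dataset.relative_change
    if np.allclose(x, x[0]):
        raise ValueError("degenerate dataset: all before-ratios equal")

    if mode == "mean":
        after = dataset.ratio_after
        return SetPointFit(
            float(after.mean()),
            float(after.std(ddof=1) / math.sqrt(len(after))),
            after - after.mean(),
        )
    if mode != "fit":
        raise ValueError(f"unknown mode {mode!r}")

    def residuals(p: np.ndarray) -> np.ndarray:
        return np.log(homeostatic_relative_change(x, abs(p[0]) + 1e-300)) - np.log(y)

    x0 = max(float(np.median(dataset.ratio_after)), 1e-6)
    sol = least_squares(residuals, x0=[x0], xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"set-point fit failed: {sol.message}")
    res = residuals(sol.x)
    dof = max(len(x) - 1, 1)
    jtj = float(np.sum(sol.jac**2))
    se = math.sqrt(float(res @ res) / dof / jtj) if jtj > 0 else float("nan")
    return SetPointFit(float(sol.x[0]), se, res)


class SPSCStats(NamedTuple):
    frequency_ratio: float
    amplitude_ratio: float


def spsc_stats(before: SPSCSample, after: SPSCSample) -> SPSCStats:
    """(rate after/before, mean amplitude after/before) for sPSC samples.

    Frequency indexes presynaptic release; amplitude indexes postsynaptic
    sensitivity.  A presynaptic plasticity episode moves the first and not
    the second.
    """
    if len(before.times_ms) == 0 or len(after.times_ms) == 0:
        raise ValueError("spsc_stats requires non-empty samples")
    return SPSCStats(
        frequency_ratio=after.rate_hz / before.rate_hz,
        amplitude_ratio=float(after.amplitudes.mean() / before.amplitudes.mean()),
    )
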