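"""Synthetic-data generators replacing the electrophysiology recordings.

Everything the analysis pipeline consumes can be generated here without any
external data: muscle-cell populations with a homogeneous membrane
conductance density (196 +/- 14 pS/pF) over a wide capacitance range,
synapses whose evoked conductance scales linearly with the cell's input
conductance, Poisson spontaneous-PSC trains with lognormal amplitudes, and
before/after Gsyn/Gin datasets following the perfect-homeostasis relation
(or its ryanodine-broken variant).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import HomeostasisDataset, SPSCSample
from .membrane import KirModel, LeakModel, MuscleCell
from .plasticity import Synapse

__all__ = [
    "PopulationSpec",
    "generate_cell_population",
    "generate_spsc_train",
    "generate_homeostasis_dataset",
    "conductance_density_slope",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of a synthetic muscle-cell/synapse population.

    ``density_mean`` is the total membrane conductance per unit capacitance;
    ``density_noise_cv`` its multiplicative cell-to-cell scatter.  Synaptic
    strength is drawn around ``synapse_ratio_mean`` times the cell's resting
    input conductance with lognormal scatter ``synapse_ratio_cv`` (the linear
    Gsyn-vs-Gin scaling seen across synaptic pairs).
    """

    n_cells: int = 19
    capacitance_min: float = 100.0  # pF
    capacitance_max: float = 1000.0  # pF
    density_mean: float = 196.0  # pS/pF
    density_noise_cv: float = 0.07
    leak_fraction: float = 0.25  # leak share of resting conductance (Kir dominates)
    synapse_ratio_mean: float = 2.36
    synapse_ratio_cv: float = 0.25
    quantal_conductance: float = 1.0  # nS
    n_quanta: int = 100
    spont_rate: float = 0.15  # Hz

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.density_mean <= 0:
            raise ValueError("density_mean must be > 0")
        if not 0 < self.capacitance_min <= self.capacitance_max:
            raise ValueError("need 0 < capacitance_min <= capacitance_max")
        if not 0 < self.leak_fraction < 1:
            raise ValueError("leak_fraction must be in (0, 1)")


def generate_cell_population(spec: PopulationSpec, seed: int) -> list[tuple[MuscleCell, Synapse]]:
    """Draw a reproducible population of (muscle cell, synapse) pairs.

    Each cell's resting conductance is density * capacitance (with
    multiplicative Gaussian density noise), split between passive leak and
    Kir so that Kir carries 1 - leak_fraction of the resting conductance
    (the gate sits at 0.5 at rest, hence gmax is twice the Kir share).
    """
    rng = np.random.default_rng(seed)
    caps = rng.uniform(spec.capacitance_min, spec.capacitance_max, spec.n_cells)
    densities = spec.density_mean * (1.0 + spec.density_noise_cv * rng.standard_normal(spec.n_cells))
    if np.any(densities <= 0):
        raise ValueError("density noise produced a non-positive conductance density")
    sigma = np.sqrt(np.log1p(spec.synapse_ratio_cv**2))
    ratios = spec.synapse_ratio_mean * rng.lognormal(-0.5 * sigma**2, sigma, spec.n_cells)

    out = []
    for cap, dens, ratio in zip(caps, densities, ratios):
        g_total = dens * cap * 1e-3  # nS
        gleak = spec.leak_fraction * g_total
        gmax = 2.0 * (1.0 - spec.leak_fraction) * g_total
        cell = MuscleCell(capacitance=cap, leak=LeakModel(gleak=gleak), kir=KirModel(gmax=gmax))
        release = ratio * g_total / (spec.n_quanta * spec.quantal_conductance)
        syn = Synapse(
            release_scale=release,
            quantal_conductance=spec.quantal_conductance,
            n_quanta=spec.n_quanta,
            spont_rate=spec.spont_rate,
        )
        out.append((cell, syn))
    return out


def conductance_density_slope(population: list[tuple[MuscleCell, Synapse]]) -> float:
    """OLS slope (pS/pF) of resting membrane conductance against capacitance.

    The measurement applied to a conductance-vs-capacitance scatter: with a
    homogeneous density the slope recovers it.
    """
    caps = np.array([c.capacitance for c, _ in population])
    g_ns = np.array([c.leak.gleak + 0.5 * c.kir.gmax for c, _ in population])  # resting Gin
    slope = np.polyfit(caps, g_ns * 1e3, 1)[0]  # nS -> pS
    return float(slope)


def generate_spsc_train(
    rate_hz: float,
    duration_s: float,
    seed: int,
    amplitude_mean: float = 1.0,
    amplitude_cv: float = 0.3,
) -> SPSCSample:
    """Poisson spontaneous-PSC train with lognormal amplitudes.

    The default rate for these synapses is low (~0.1-0.2 Hz); a zero
    duration returns an empty (flagged-by-emptiness) sample.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be > 0")
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    rng = np.random.default_rng(seed)
    if duration_s == 0:
        return SPSCSample(np.empty(0), np.empty(0), 0.0)
    n = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s * 1000.0, n))
    sigma = np.sqrt(np.log1p(amplitude_cv**2))
    amps = amplitude_mean * rng.lognormal(-0.5 * sigma**2, sigma, n)
    return SPSCSample(times, amps, duration_s * 1000.0)


def generate_homeostasis_dataset(
    n: int,
    seed: int,
    set_point: float = 2.36,
    ratio_before_range: tuple[float, float] = (0.8, 6.0),
    noise_sd: float = 0.10,
    mode: str = "control",
    ryanodine_uplift: float = 1.5,
) -> HomeostasisDataset:
    """Before/after Gsyn/Gin pairs under the homeostatic (or broken) rule.

    mode="control": ratio_after = set_point * lognormal noise (perfect
    homeostasis, every synapse lands on the set point up to measurement
    noise; the population spread contracts).  mode="ryanodine": the
    depression arm is disabled, ratio_after = ratio_before * uplift * noise
    (no convergence; the spread grows).
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if mode not in ("control", "ryanodine"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    before = rng.uniform(*ratio_before_range, n)
    noise = rng.lognormal(0.0, noise_sd, n) if noise_sd > 0 else np.ones(n)
    if mode == "control":
        after = set_point * noise
    else:
        after = before * ryanodine_uplift * noise
    return HomeostasisDataset(before, after, condition=mode)
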