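"""Run configuration: schema-validated parameter files for reproducible runs.

A run is fully described by (config, seed).  The config collects the model
parameters of every module plus the protocol selection; unknown keys are
rejected, units are validated by the underlying domain types, and every run
writes the fully resolved config next to its outputs so results can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = ["RunConfig", "load_config"]


class CellConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    capacitance_pF: float = Field(100.0, gt=0)
    density_pS_per_pF: float = Field(196.0, gt=0)
    leak_fraction: float = Field(0.25, gt=0, lt=1)
    Eleak_mV: float = -80.0
    EK_mV: float = -80.0
    kir_slope_per_mV: float = Field(0.074, gt=0)
    kir_tau_ms: float = Field(0.2, gt=0)
    spike_threshold_mV: float = -63.0
    ap_peak_mV: float = 30.0
    refractory_ms: float = Field(15.0, gt=0)


class SynapseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    ratio: float = Field(2.36, gt=0)  # initial Gsyn/Gin
    quantal_conductance_nS: float = Field(1.0, gt=0)
    n_quanta: int = Field(100, gt=0)
    spont_rate_hz: float = Field(0.15, gt=0)
    tau_rise_ms: float = Field(0.3, gt=0)
    tau_decay_ms: float = Field(3.0, gt=0)


class SensorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dicr_threshold_mV: float = -40.0
    dicr_v_half_mV: float = -15.0
    dicr_v_slope_mV: float = Field(7.0, gt=0)
    dicr_amplitude: float = Field(1.0, gt=0)
    dicr_tau_ms: float = Field(50.0, gt=0)
    nico_flux_gain: float = Field(1.5e-3, ge=0)
    nico_tau_ms: float = Field(4000.0, gt=0)
    nico_ca_reversal_mV: float = 120.0
    nico_g_sat_nS: float = Field(1.0, gt=0)
    pca_over_pna: float = Field(0.23, gt=0)


class RunConfig(BaseModel):
    """Top-level run description."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    dt_ms: float = Field(0.05, gt=0)
    set_point: float = Field(2.36, gt=0)
    protocol: str = "chronic_activity"
    protocol_overrides: dict = Field(default_factory=dict)
    outdir: str = "runs"
    cell: CellConfig = Field(default_factory=CellConfig)
    synapse: SynapseConfig = Field(default_factory=SynapseConfig)
    sensors: SensorConfig = Field(default_factory=SensorConfig)

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if not 0 <= v < 2**31:
            raise ValueError("seed must be in [0, 2^31)")
        return v

    # -- builders ----------------------------------------------------------

    def build_cell(self):
        from .membrane import KirModel, LeakModel, MuscleCell, SpikeMechanism

        c = self.cell
        g_total = c.density_pS_per_pF * c.capacitance_pF * 1e-3
        return MuscleCell(
            capacitance=c.capacitance_pF,
            leak=LeakModel(gleak=c.leak_fraction * g_total, Eleak=c.Eleak_mV),
            kir=KirModel(
                gmax=2.0 * (1.0 - c.leak_fraction) * g_total,
                EK=c.EK_mV,
                slope=c.kir_slope_per_mV,
                tau_m=c.kir_tau_ms,
            ),
            spike=SpikeMechanism(
                threshold=c.spike_threshold_mV,
                ap_peak=c.ap_peak_mV,
                refractory_ms=c.refractory_ms,
            ),
        )

    def build_synapse(self, cell=None):
        from .membrane import input_conductance, resting_potential
        from .plasticity import Synapse

        cell = cell or self.build_cell()
        s = self.synapse
        gin = input_conductance(cell, resting_potential(cell))
        return Synapse(
            release_scale=self.synapse.ratio * gin / (s.n_quanta * s.quantal_conductance_nS),
            quantal_conductance=s.quantal_conductance_nS,
            n_quanta=s.n_quanta,
            spont_rate=s.spont_rate_hz,
            tau_rise=s.tau_rise_ms,
            tau_decay=s.tau_decay_ms,
        )

    def build_sensors(self):
        from .sensors import DICRSensor, NicotinicCaSensor

        s = self.sensors
        nico = NicotinicCaSensor(
            flux_gain=s.nico_flux_gain,
            tau_decay=s.nico_tau_ms,
            ca_reversal=s.nico_ca_reversal_mV,
            g_sat=s.nico_g_sat_nS,
            pca_ratio=s.pca_over_pna,
        )
        dicr = DICRSensor(
            threshold=s.dicr_threshold_mV,
            v_half=s.dicr_v_half_mV,
            v_slope=s.dicr_v_slope_mV,
            amplitude=s.dicr_amplitude,
            tau_decay=s.dicr_tau_ms,
        )
        return nico, dicr

    def resolved_json(self) -> str:
        return json.dumps(self.model_dump(), indent=2, sort_keys=True)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML or TOML run config; None/empty -> defaults.

    Unknown keys raise a validation error naming the offending fields.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return RunConfig()
    if path.suffix in (".toml", ".tml"):
        data = tomllib.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    return RunConfig.model_validate(data)
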