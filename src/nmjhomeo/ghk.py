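"""Extended Goldman–Hodgkin–Katz reversal potentials for the muscle nicotinic channel.

The endplate nicotinic receptor-channel is a non-selective cation channel
permeant to Na+, K+, Ca2+ and Mg2+.  Its reversal potential in a given pair of
ionic media follows an extended GHK voltage equation in which monovalent and
divalent species carry fixed activity coefficients (0.75 and 0.25) and the
divalent terms carry an additional weight of 4 (the low-internal-divalent
limit of the full constant-field treatment of divalent permeation)::

    Vrev = (RT/F) * ln(num / den)

    num = 0.75*PK*[K]o  + 0.75*PNa*[Na]o + 0.25*4*PCa*[Ca]o + 0.25*4*PMg*[Mg]o
    den = 0.75*PK*[K]i  + 0.75*PNa*[Na]i + 0.25*4*PCa*[Ca]i + 0.25*4*PMg*[Mg]i

Only the permeability ratios PK/PNa, PCa/PNa and PMg/PNa are identifiable from
reversal potentials; the forward computation and the inverse (least-squares)
fit both work in ratio form.  Default ratios are 1.07, 0.23 and 0.31, the
values obtained for the embryonic Xenopus muscle nicotinic channel.

The divalent x4 weighting is applied symmetrically on both membrane sides; in
the standard internal medium [Ca]i is ~0 so the internal Ca term vanishes.
Chloride is not permeant in this model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "IonicMedium",
    "PermeabilityRatios",
    "GHKConstants",
    "GHKDomainError",
    "IdentifiabilityWarning",
    "FitResult",
    "ghk_reversal",
    "fit_permeability_ratios",
    "default_measurement_media",
]

R_GAS = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol


class GHKDomainError(ValueError):
    """Raised when a medium pair gives a non-positive flux sum on one side."""


class IdentifiabilityWarning(UserWarning):
    """Emitted when a fitting design cannot constrain all permeability ratios."""


@dataclass(frozen=True)
class IonicMedium:
    """Ionic composition of one compartment (concentrations in mM)."""

    Na: float
    K: float
    Ca: float = 0.0
    Mg: float = 0.0
    side: str = "external"

    def __post_init__(self) -> None:
        for name in ("Na", "K", "Ca", "Mg"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} concentration must be finite and >= 0, got {value}")
        if self.side not in ("internal", "external"):
            raise ValueError(f"side must be 'internal' or 'external', got {self.side!r}")


@dataclass(frozen=True)
class PermeabilityRatios:
    """Permeability of K+, Ca2+ and Mg2+ relative to Na+ (dimensionless, > 0)."""

    pK_over_pNa: float = 1.07
    pCa_over_pNa: float = 0.23
    pMg_over_pNa: float = 0.31

    def __post_init__(self) -> None:
        for name in ("pK_over_pNa", "pCa_over_pNa", "pMg_over_pNa"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value}")

    def as_array(self) -> np.ndarray:
        return np.array([self.pK_over_pNa, self.pCa_over_pNa, self.pMg_over_pNa])


@dataclass(frozen=True)
class GHKConstants:
    """Physical constants of the extended GHK equation.

    ``monovalent_activity`` and ``divalent_activity`` are the fixed ionic
    activity coefficients (0.75 / 0.25); ``divalent_weight`` is the factor 4
    multiplying divalent permeability terms.
    """

    temperature: float = 293.15  # K, room temperature
    monovalent_activity: float = 0.75
    divalent_activity: float = 0.25
    divalent_weight: float = 4.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 K")
        for name in ("monovalent_activity", "divalent_activity"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {value}")

    @property
    def thermal_voltage_mV(self) -> float:
        """RT/F in millivolts."""
        return 1000.0 * R_GAS * self.temperature / FARADAY


def _flux_sum(medium: IonicMedium, ratios: PermeabilityRatios, constants: GHKConstants) -> float:
    """Permeability-weighted concentration sum for one side, in units of PNa."""
    mono = constants.monovalent_activity
    diva = constants.divalent_activity * constants.divalent_weight
    return (
        mono * ratios.pK_over_pNa * medium.K
        + mono * medium.Na
        + diva * ratios.pCa_over_pNa * medium.Ca
        + diva * ratios.pMg_over_pNa * medium.Mg
    )


def ghk_reversal(
    internal: IonicMedium,
    external: IonicMedium,
    ratios: PermeabilityRatios | None = None,
    constants: GHKConstants | None = None,
) -> float:
    """Reversal potential (mV) of the nicotinic current between two media.

    Raises :class:`GHKDomainError` when either side has zero permeant flux
    (the log argument would be 0 or infinite).
    """
    ratios = ratios or PermeabilityRatios()
    constants = constants or GHKConstants()
    num = _flux_sum(external, ratios, constants)
    den = _flux_sum(internal, ratios, constants)
    if num <= 0 or den <= 0:
        raise GHKDomainError(
            "degenerate medium: zero permeant flux on "
            + ("both sides" if num <= 0 and den <= 0 else "the external side" if num <= 0 else "the internal side")
        )
    return constants.thermal_voltage_mV * math.log(num / den)


class Measurement(NamedTuple):
    """One (media pair, reversal potential) observation."""

    internal: IonicMedium
    external: IonicMedium
    vrev_mV: float


class FitResult(NamedTuple):
    """Outcome of a permeability-ratio fit."""

    ratios: PermeabilityRatios
    residuals_mV: np.ndarray
    rms_mV: float
    identifiable: bool


def _coerce(measurements: Iterable) -> list[Measurement]:
    out = []
    for m in measurements:
        if isinstance(m, Measurement):
            out.append(m)
        else:
            internal, external, vrev = m
            out.append(Measurement(internal, external, float(vrev)))
    return out


def fit_permeability_ratios(
    measurements: Sequence,
    constants: GHKConstants | None = None,
    rank_tol: float = 1e-6,
) -> FitResult:
    """Least-squares fit of (PK/PNa, PCa/PNa, PMg/PNa) to reversal potentials.

    Measurements are triples ``(internal, external, vrev_mV)``.  The fit runs
    in log-ratio space (positivity enforced by construction) from the fixed
    initial guess of all ratios equal to 1.  On noiseless forward-generated
    data the generating ratios are recovered to machine-fit tolerance.

    A rank-deficient sensitivity matrix at the solution (a design that cannot
    constrain all three ratios) produces an :class:`IdentifiabilityWarning`
    and ``identifiable=False`` in the result; non-convergence raises
    ``RuntimeError``.
    """
    constants = constants or GHKConstants()
    obs = _coerce(measurements)
    if len(obs) == 0:
        raise ValueError("at least one measurement is required")
    target = np.array([m.vrev_mV for m in obs])

    def residuals(log_ratios: np.ndarray) -> np.ndarray:
        r = PermeabilityRatios(*np.exp(log_ratios))
        model = np.array([ghk_reversal(m.internal, m.external, r, constants) for m in obs])
        return model - target

    sol = least_squares(residuals, x0=np.zeros(3), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"permeability fit failed to converge: {sol.message}")

    singular = np.linalg.svd(sol.jac, compute_uv=False)
    identifiable = bool(len(obs) >= 3 and singular.min() > rank_tol * max(singular.max(), 1.0))
    if not identifiable:
        warnings.warn(
            "measurement design does not constrain all three permeability ratios "
            "(rank-deficient sensitivity); returned ratios are one of many equivalent fits",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    res = residuals(sol.x)
    return FitResult(
        ratios=PermeabilityRatios(*np.exp(sol.x)),
        residuals_mV=res,
        rms_mV=float(np.sqrt(np.mean(res**2))),
        identifiable=identifiable,
    )


#: Standard internal (pipette) medium: 3 Na / 110 K / 2 Mg, no Ca.
STANDARD_INTERNAL = IonicMedium(Na=3.0, K=110.0, Ca=0.0, Mg=2.0, side="internal")

#: Standard external physiological medium.
STANDARD_EXTERNAL = IonicMedium(Na=140.0, K=3.0, Ca=2.0, Mg=1.0, side="external")


def default_measurement_media() -> list[tuple[IonicMedium, IonicMedium]]:
    """Synthetic six-media reversal-potential design (internal, external) pairs.

    A stand-in design constructed so that Na+, K+, Ca2+ and Mg2+ each vary
    across external media, which makes the three permeability ratios jointly
    identifiable.  It is a synthetic fixture, not a transcription of any
    recorded media table.
    """
    externals = [
        STANDARD_EXTERNAL,
        IonicMedium(Na=100.0, K=40.0, Ca=2.0, Mg=1.0),
        IonicMedium(Na=35.0, K=3.0, Ca=2.0, Mg=1.0),
        IonicMedium(Na=50.0, K=3.0, Ca=60.0, Mg=1.0),
        IonicMedium(Na=50.0, K=3.0, Ca=2.0, Mg=60.0),
        IonicMedium(Na=10.0, K=120.0, Ca=2.0, Mg=1.0),
    ]
    return [(STANDARD_INTERNAL, ext) for ext in externals]


def forward_generate(
    media: Sequence[tuple[IonicMedium, IonicMedium]] | None = None,
    ratios: PermeabilityRatios | None = None,
    constants: GHKConstants | None = None,
) -> list[Measurement]:
    """Forward-compute noiseless measurements for a media design."""
    media = media if media is not None else default_measurement_media()
    ratios = ratios or PermeabilityRatios()
    return [
        Measurement(internal, external, ghk_reversal(internal, external, ratios, constants))
        for internal, external in media
    ]
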