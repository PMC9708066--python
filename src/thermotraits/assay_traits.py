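"""Derive physiological traits from raw culture-assay measurements.

A growth-respiration assay starts from an exponentially growing culture of
known cell density, lets it grow for a few hours at the assay temperature
while cumulative respired carbon is captured, and brackets the incubation
with flow-cytometry cell counts / diameters and luminescence (RLU) ATP
readings.  The functions here convert those raw measurements into the
traits used downstream:

* carbon biomass of the culture, from cell counts and mean cell volume
  (cells treated as spheres; carbon per cell from the allometric relation
  fgC = 133.754 * V**0.438 with V in µm³);
* mass-specific exponential growth rate  mu = ln(Ctot/C0) / t  (per hour);
* biomass-specific respiration rate  R = mu * Rtot / (C0 * exp(mu*t) - C0),
  which accounts for the biomass changing while carbon is respired;
* ATP concentration from the peak RLU reading via the calibration
  log10(nM ATP) = 1.21 * log10(RLU) - 4.69, and its ratio to biomass.

All biomass values are in femtograms of carbon (fgC); ``Rtot`` must be
supplied in the same unit.  Negative growth rates (shrinking cultures) are
permitted and propagate through the respiration equation unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AssayRecord",
    "DerivedTraits",
    "sphere_volume",
    "carbon_per_cell",
    "culture_biomass",
    "growth_rate",
    "respiration_rate",
    "atp_concentration",
    "atp_per_biomass",
    "derive_traits",
]

#: coefficient and exponent of the cell-volume -> carbon allometry
CARBON_COEF = 133.754
CARBON_EXP = 0.438

#: slope and intercept of the log10 RLU -> log10 nM ATP calibration
ATP_CAL_SLOPE = 1.21
ATP_CAL_INTERCEPT = -4.69

#: |mu * t| below which the respiration equation switches to its
#: analytic zero-growth limit Rtot / (C0 * t)
MU_T_EPSILON = 1e-8


@dataclass
class AssayRecord:
    """One replicate's raw measurements.

    ``diameters`` may hold per-cell measurements or a single mean; ``Rtot``
    is cumulative respired carbon in the same mass unit as biomass (fgC).
    ``rlu_series`` is a list of ``(minutes, RLU)`` luminescence readings.
    """

    isolate_id: str
    assay_temp: float  # degC
    t: float  # hours
    initial_count: float
    final_count: float
    diameters: Sequence[float]  # um
    Rtot: float  # fgC
    rlu_series: Sequence[tuple[float, float]] = field(default_factory=list)
    od600: float | None = None
    replicate: str = "1"

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError("assay duration t must be positive")
        if self.initial_count <= 0 or self.final_count <= 0:
            raise ValueError("cell counts must be positive")
        if len(self.diameters) == 0 or any(d <= 0 for d in self.diameters):
            raise ValueError("diameters must be non-empty and positive")
        if self.Rtot < 0:
            raise ValueError("Rtot must be non-negative")


@dataclass
class DerivedTraits:
    """Traits derived from one :class:`AssayRecord`."""

    isolate_id: str
    assay_temp: float
    C0: float  # fgC
    Ctot: float  # fgC
    mu: float  # per hour
    R: float  # per hour
    atp: float | None  # nM
    atp_per_biomass: float | None
    mean_cell_volume: float  # um^3
    replicate: str = "1"


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere of the given diameter (µm -> µm³)."""
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi * diameter**3 / 6.0


def carbon_per_cell(volume: float) -> float:
    """Cellular carbon content (fgC) from cell volume (µm³).

    Allometric relation fgC = 133.754 * V**0.438.
    """
    if volume < 0:
        raise ValueError("volume must be non-negative")
    return CARBON_COEF * volume**CARBON_EXP


def culture_biomass(count: float, mean_volume: float) -> float:
    """Carbon biomass (fgC) of ``count`` cells of mean volume ``mean_volume``."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return count * carbon_per_cell(mean_volume)


def growth_rate(C0: float, Ctot: float, t: float) -> float:
    """Mass-specific exponential growth rate mu = ln(Ctot / C0) / t.

    Negative when the culture shrank (Ctot < C0).
    """
    if C0 <= 0 or Ctot <= 0:
        raise ValueError("biomass values must be positive")
    if t <= 0:
        raise ValueError("duration must be positive")
    return math.log(Ctot / C0) / t


def respiration_rate(mu: float, Rtot: float, C0: float, t: float) -> float:
    """Biomass-specific respiration rate of a growing culture.

    R = mu * Rtot / (C0 * exp(mu t) - C0); the denominator integrates the
    exponentially changing biomass over the assay.  Near mu = 0 (|mu t|
    below :data:`MU_T_EPSILON`) the analytic limit Rtot / (C0 t) is used.
    """
    if C0 <= 0:
        raise ValueError("C0 must be positive")
    if t <= 0:
        raise ValueError("duration must be positive")
    if Rtot < 0:
        raise ValueError("Rtot must be non-negative")
    if abs(mu * t) < MU_T_EPSILON:
        return Rtot / (C0 * t)
    return mu * Rtot / (C0 * math.expm1(mu * t))


def atp_concentration(rlu_series: Sequence[tuple[float, float]]) -> float:
    """ATP concentration (nM) from a luminescence time series.

    The reaction develops over a few minutes, so the peak relative-light-unit
    reading is taken and inverted through the calibration
    log10(nM) = 1.21 * log10(RLU) - 4.69.
    """
    if len(rlu_series) == 0:
        raise ValueError("rlu_series must be non-empty")
    rlus = np.asarray([r for _, r in rlu_series], dtype=float)
    if np.any(rlus <= 0):
        raise ValueError("RLU readings must be positive")
    peak = float(rlus.max())
    return 10.0 ** (ATP_CAL_SLOPE * math.log10(peak) + ATP_CAL_INTERCEPT)


def atp_per_biomass(atp: float, biomass: float) -> float:
    """ATP concentration normalised by culture biomass (nM per fgC)."""
    if biomass <= 0:
        raise ValueError("biomass must be positive")
    return atp / biomass


def derive_traits(record: AssayRecord) -> DerivedTraits:
    """Run the full derivation chain on one assay record."""
    mean_volume = float(np.mean([sphere_volume(d) for d in record.diameters]))
    C0 = culture_biomass(record.initial_count, mean_volume)
    Ctot = culture_biomass(record.final_count, mean_volume)
    mu = growth_rate(C0, Ctot, record.t)
    R = respiration_rate(mu, record.Rtot, C0, record.t)
    if len(record.rlu_series) > 0:
        atp = atp_concentration(record.rlu_series)
        atp_ratio = atp_per_biomass(atp, Ctot)
    else:
        atp = None
        atp_ratio = None
    return DerivedTraits(
        isolate_id=record.isolate_id,
        assay_temp=record.assay_temp,
        C0=C0,
        Ctot=Ctot,
        mu=mu,
        R=R,
        atp=atp,
        atp_per_biomass=atp_ratio,
        mean_cell_volume=mean_volume,
        replicate=record.replicate,
    )
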