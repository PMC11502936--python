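"""Forest energy budgets and squirrel carrying-capacity estimates.

Per-m2 energy densities are extrapolated to stand areas: available energy
over the full mature area of each species, consumed energy over the area
actually occupied by squirrels (which can differ by species and year —
e.g. a year in which no spruce consumption was recorded has a zero
occupied spruce area). Energy totals divide by a squirrel's daily energy
requirement over a one-year horizon to give a head count; the lower bound
uses the high (700 kJ/day) requirement and the upper bound the low
(400 kJ/day) one. An independent area-based estimate multiplies the mature
area by a literature density of 0.32 squirrels/ha.

All squirrel counts round half away from zero, matching the published
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .cone_energy import EnergyDensity
from .survey_io import M2_PER_HA, AnalysisConfig, Species, round_half_away

__all__ = [
    "SpeciesEnergy",
    "ForestEnergy",
    "CapacityEstimate",
    "total_energy",
    "forest_energy",
    "squirrels_from_energy",
    "capacity_estimate",
    "area_based_capacity",
]


@dataclass(frozen=True)
class SpeciesEnergy:
    """Energy totals for one species in one year."""

    mature_area_ha: float
    occupied_area_ha: float
    total_available_kJ: float
    total_consumed_kJ: float


@dataclass(frozen=True)
class ForestEnergy:
    """Whole-forest energy budget for one survey year."""

    year: int
    species: dict[Species, SpeciesEnergy] = field(default_factory=dict)

    @property
    def total_available_kJ(self) -> float:
        return sum(s.total_available_kJ for s in self.species.values())

    @property
    def total_consumed_kJ(self) -> float:
        return sum(s.total_consumed_kJ for s in self.species.values())

    @property
    def mature_area_ha(self) -> float:
        return sum(s.mature_area_ha for s in self.species.values())

    @property
    def percent_consumed(self) -> float:
        """Consumed energy as a percentage of available energy."""
        avail = self.total_available_kJ
        if avail <= 0:
            return 0.0
        return 100.0 * self.total_consumed_kJ / avail


@dataclass(frozen=True)
class CapacityEstimate:
    """Energy-based (feeding survey) and area-based squirrel numbers."""

    year: int
    fs_capacity_low: int
    fs_capacity_high: int
    fs_actual_low: int
    fs_actual_high: int
    area_capacity: int

    def __post_init__(self) -> None:
        if self.fs_capacity_low > self.fs_capacity_high:
            raise ValueError("fs_capacity_low exceeds fs_capacity_high")
        if self.fs_actual_low > self.fs_actual_high:
            raise ValueError("fs_actual_low exceeds fs_actual_high")
        if min(
            self.fs_capacity_low,
            self.fs_actual_low,
            self.area_capacity,
        ) < 0:
            raise ValueError("squirrel counts cannot be negative")


def total_energy(energy_per_m2_kJ: float, area_ha: float) -> float:
    """Extrapolate an energy density to an area: kJ/m2 x ha x 10,000."""
    if energy_per_m2_kJ < 0 or area_ha < 0:
        raise ValueError("energy density and area must be non-negative")
    return energy_per_m2_kJ * area_ha * M2_PER_HA


def forest_energy(
    densities: Sequence[EnergyDensity],
    areas: Mapping[Species, tuple[float, Optional[float]]],
    year: int,
) -> ForestEnergy:
    """Assemble the per-year forest energy budget.

    ``areas`` maps species to ``(mature_ha, occupied_ha)``. An occupied
    area of ``None`` defaults to the mature area — the convention for a
    survey in which squirrel signs were found in every surveyed stand.
    """
    per_species: dict[Species, SpeciesEnergy] = {}
    for d in densities:
        if d.year != year:
            raise ValueError(f"density for year {d.year} passed to forest_energy(year={year})")
        if d.species not in areas:
            raise ValueError(f"no area entry for {d.species.value} in year {year}")
        mature_ha, occupied_ha = areas[d.species]
        if occupied_ha is None:
            occupied_ha = mature_ha
        per_species[d.species] = SpeciesEnergy(
            mature_area_ha=mature_ha,
            occupied_area_ha=occupied_ha,
            total_available_kJ=total_energy(d.energy_per_m2_available_kJ, mature_ha),
            total_consumed_kJ=total_energy(d.energy_per_m2_consumed_kJ, occupied_ha),
        )
    return ForestEnergy(year=year, species=per_species)


def squirrels_from_energy(total_kJ: float, daily_req_kJ: float, horizon_days: int) -> int:
    """Number of squirrels an energy total can sustain over the horizon."""
    if daily_req_kJ <= 0 or horizon_days <= 0:
        raise ValueError("daily requirement and horizon must be positive")
    if total_kJ < 0:
        raise ValueError("total energy cannot be negative")
    return round_half_away(total_kJ / (daily_req_kJ * horizon_days))


def capacity_estimate(fe: ForestEnergy, cfg: AnalysisConfig) -> CapacityEstimate:
    """Convert a forest energy budget into squirrel-number estimates.

    Carrying capacity comes from available energy, the actual-population
    estimate from consumed energy; each is an interval whose lower bound
    assumes the high daily requirement and vice versa.
    """
    return CapacityEstimate(
        year=fe.year,
        fs_capacity_low=squirrels_from_energy(
            fe.total_available_kJ, cfg.daily_requirement_high_kJ, cfg.horizon_days
        ),
        fs_capacity_high=squirrels_from_energy(
            fe.total_available_kJ, cfg.daily_requirement_low_kJ, cfg.horizon_days
        ),
        fs_actual_low=squirrels_from_energy(
            fe.total_consumed_kJ, cfg.daily_requirement_high_kJ, cfg.horizon_days
        ),
        fs_actual_high=squirrels_from_energy(
            fe.total_consumed_kJ, cfg.daily_requirement_low_kJ, cfg.horizon_days
        ),
        area_capacity=area_based_capacity(fe.mature_area_ha, cfg.area_density_per_ha),
    )


def area_based_capacity(mature_area_ha: float, density_per_ha: float) -> int:
    """Squirrel capacity from mature area alone (density x area)."""
    if mature_area_ha < 0 or density_per_ha < 0:
        raise ValueError("area and density must be non-negative")
    return round_half_away(mature_area_ha * density_per_ha)
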