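"""Stand classification, area ledgers and composition correction.

A conifer stand becomes a usable cone producer ("mature") at 25 years of
age; younger stands, felled or burned ground and non-conifer cover cannot
sustain squirrels. The per-year area ledger tabulates hectares by class.

The composition-correction step transfers a known Sitka-spruce :
lodgepole-pine tree ratio from a reference stand to another stand via
their relative cone productions:

    R_ss1 = (C_ss1 * C_lp2 * R_ss2) / (C_lp1 * C_ss2)

where C are per-m2 cone densities and R the spruce:pine tree ratios. The
corrected ratio then reallocates a stand's mapped area between the two
species.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .survey_io import (
    CONIFERS,
    AnalysisConfig,
    Species,
    StandSnapshot,
    StandStatus,
    round_half_away,
)

__all__ = [
    "StandClass",
    "AreaLedgerRow",
    "CompositionRatio",
    "ClassificationError",
    "classify_stand",
    "tabulate_areas",
    "species_areas",
    "composition_ratio",
    "reallocate_stand_area",
    "percent_reduction",
]


class StandClass(str, enum.Enum):
    MATURE = "mature"
    IMMATURE = "immature"
    UNSUITABLE = "unsuitable"
    BROADLEAF = "broadleaf"


class ClassificationError(ValueError):
    """A stand cannot be classified from the information given."""


@dataclass(frozen=True)
class AreaLedgerRow:
    """One year of the forest composition ledger (hectares, unrounded)."""

    year: int
    broadleaf_ha: float
    sitka_ha: float
    lodgepole_ha: float
    unsuitable_ha: float

    @property
    def mature_conifer_ha(self) -> float:
        return self.sitka_ha + self.lodgepole_ha

    @property
    def total_ha(self) -> float:
        return self.broadleaf_ha + self.mature_conifer_ha + self.unsuitable_ha

    def rounded(self) -> tuple[int, int, int, int, int]:
        """(broadleaf, sitka, lodgepole, mature conifer, unsuitable), nearest ha."""
        return (
            round_half_away(self.broadleaf_ha),
            round_half_away(self.sitka_ha),
            round_half_away(self.lodgepole_ha),
            round_half_away(self.mature_conifer_ha),
            round_half_away(self.unsuitable_ha),
        )


@dataclass(frozen=True)
class CompositionRatio:
    """A stand's Sitka spruce : lodgepole pine tree ratio."""

    stand_id: str
    r_ss: float

    def __post_init__(self) -> None:
        if self.r_ss <= 0:
            raise ValueError("a composition ratio must be positive")


def classify_stand(s: StandSnapshot, cfg: AnalysisConfig) -> StandClass:
    """Classify a stand snapshot into the ledger categories.

    Burned, felled and bare ground is unsuitable regardless of age.
    Conifers with a planting year are mature from ``maturity_age_years``
    (inclusive); without one, an explicit mature/immature status is
    required.
    """
    if s.status in (StandStatus.BARE_OR_FELLED, StandStatus.BURNED):
        return StandClass.UNSUITABLE
    if s.status is StandStatus.BROADLEAF_RESERVE or s.species is Species.BROADLEAF:
        return StandClass.BROADLEAF
    if s.species not in CONIFERS:
        return StandClass.UNSUITABLE
    if s.planting_year is not None:
        age = s.year - s.planting_year
        return StandClass.MATURE if age >= cfg.maturity_age_years else StandClass.IMMATURE
    if s.status in (StandStatus.MATURE, StandStatus.IMMATURE):
        return StandClass.MATURE if s.status is StandStatus.MATURE else StandClass.IMMATURE
    raise ClassificationError(
        f"stand {s.stand_id}: conifer without planting_year or explicit mature/immature status"
    )


def tabulate_areas(stands: Sequence[StandSnapshot], cfg: AnalysisConfig) -> AreaLedgerRow:
    """Sum one year's stand areas into a ledger row.

    Immature conifers are pooled with bare/felled/burned ground as
    unsuitable habitat, since neither can support a squirrel population.
    """
    if not stands:
        raise ValueError("cannot tabulate an empty stand list")
    years = {s.year for s in stands}
    if len(years) > 1:
        raise ValueError(f"stands span multiple years: {sorted(years)}")
    (year,) = years
    broadleaf = sitka = lodgepole = unsuitable = 0.0
    for s in stands:
        cls = classify_stand(s, cfg)
        if cls is StandClass.BROADLEAF:
            broadleaf += s.area_ha
        elif cls is StandClass.MATURE:
            if s.species is Species.SITKA_SPRUCE:
                sitka += s.area_ha
            else:
                lodgepole += s.area_ha
        else:  # immature or unsuitable
            unsuitable += s.area_ha
    return AreaLedgerRow(
        year=year,
        broadleaf_ha=broadleaf,
        sitka_ha=sitka,
        lodgepole_ha=lodgepole,
        unsuitable_ha=unsuitable,
    )


def species_areas(
    stands: Sequence[StandSnapshot], cfg: AnalysisConfig
) -> dict[Species, tuple[float, Optional[float]]]:
    """Per-conifer mature and occupied areas for one snapshot year.

    Returns ``{species: (mature_ha, occupied_ha)}`` where ``occupied_ha``
    is the summed area of occupied mature stands. When no stand in the
    year carries an occupancy flag, occupancy was not recorded and
    ``occupied_ha`` is ``None`` (downstream extrapolation then falls back
    to the full mature area).
    """
    if not stands:
        raise ValueError("cannot derive areas from an empty stand list")
    years = {s.year for s in stands}
    if len(years) > 1:
        raise ValueError(f"stands span multiple years: {sorted(years)}")
    any_flag = any(s.occupied for s in stands)
    out: dict[Species, tuple[float, Optional[float]]] = {}
    for species in CONIFERS:
        mature = sum(
            s.area_ha
            for s in stands
            if s.species is species and classify_stand(s, cfg) is StandClass.MATURE
        )
        occupied: Optional[float]
        if any_flag:
            occupied = sum(
                s.area_ha
                for s in stands
                if s.species is species
                and s.occupied
                and classify_stand(s, cfg) is StandClass.MATURE
            )
        else:
            occupied = None
        out[species] = (mature, occupied)
    return out


def composition_ratio(
    c_ss1: float, c_lp1: float, c_ss2: float, c_lp2: float, r_ss2: float
) -> float:
    """Spruce:pine tree ratio of stand 1 from cone densities and a reference.

    Stand 2's tree ratio ``r_ss2`` is known; both stands' per-m2 cone
    densities (``c_ss*`` spruce, ``c_lp*`` pine) are observed. A stand with
    no cones of one species cannot be corrected this way.
    """
    for name, value in (
        ("c_ss1", c_ss1),
        ("c_lp1", c_lp1),
        ("c_ss2", c_ss2),
        ("c_lp2", c_lp2),
        ("r_ss2", r_ss2),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be positive to define the ratio, got {value}")
    return (c_ss1 * c_lp2 * r_ss2) / (c_lp1 * c_ss2)


def reallocate_stand_area(area_ha: float, r_ss: float) -> tuple[float, float]:
    """Split a stand's area between spruce and pine by tree ratio.

    Returns ``(sitka_ha, lodgepole_ha)``; the parts sum to ``area_ha``
    exactly (the pine share is computed as the remainder).
    """
    if area_ha < 0:
        raise ValueError("area cannot be negative")
    if r_ss <= 0:
        raise ValueError("composition ratio must be positive")
    sitka = area_ha * r_ss / (1.0 + r_ss)
    return sitka, area_ha - sitka


def percent_reduction(before: float, after: float) -> float:
    """Percent reduction from ``before`` to ``after`` (negative = increase)."""
    if before <= 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (before - after) / before


_LEDGER_COLUMNS = [
    "year",
    "broadleaf_ha",
    "sitka_ha",
    "lodgepole_ha",
    "mature_conifer_ha",
    "unsuitable_ha",
]


def write_area_ledger(rows: Sequence[AreaLedgerRow], path) -> None:
    """Write per-year ledger rows as CSV, hectares rounded to whole numbers."""
    import csv
    from pathlib import Path

    if not rows:
        raise ValueError("cannot write an empty ledger")
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_LEDGER_COLUMNS)
        for row in rows:
            broadleaf, sitka, lodgepole, mature, unsuitable = row.rounded()
            writer.writerow([row.year, broadleaf, sitka, lodgepole, mature, unsuitable])
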