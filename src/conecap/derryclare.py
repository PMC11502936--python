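"""Published survey summaries for Derryclare forest (Connemara, Ireland).

Derryclare is a 570-ha commercial conifer forest (plus a 13-ha broadleaf
nature reserve) to which 19 red squirrels were translocated in 2005.
Ground feeding surveys were run in 2008-2011 and again in 2021; historical
stand maps give the forest's composition in each survey year. This module
packages those published summaries — the per-year area ledger, the pooled
per-m2 cone and energy densities, the occupied areas used to extrapolate
consumption, and the 2021 raw totals — as plain data, so the full analysis
can be reproduced without the original field files.

The per-transect raw data behind the pooled densities were never
published; the transect and cone-measurement tables built here are
synthetic encodings that reproduce the published totals and means exactly
(see :func:`conecap.synthetic_data.derryclare_fixture`).
"""

from __future__ import annotations

from .cone_energy import EnergyDensity
from .survey_io import Species, StandSnapshot, StandStatus

__all__ = [
    "FOREST_TOTAL_HA",
    "PLANTING_YEAR",
    "AREA_LEDGER",
    "DENSITIES",
    "OCCUPIED_AREAS_HA",
    "SURVEY_2021",
    "stand_snapshots",
    "stand_snapshots_2011_post_fire",
    "published_densities",
]

#: Commercial forest plus nature reserve, hectares.
FOREST_TOTAL_HA = 583.0

#: The conifer crop was planted in the 1960s; all stands mature by 2005.
PLANTING_YEAR = 1965

# Per-year composition ledger, hectares:
# year -> (broadleaf, sitka spruce, lodgepole pine, unsuitable).
# 2011 appears twice: before and after the April 2011 fire, which burned
# 58 ha of mature lodgepole pine. Feeding-survey extrapolations for 2011
# use the pre-fire areas (the survey preceded the loss of those stands
# from the crop base).
AREA_LEDGER: dict[int, tuple[float, float, float, float]] = {
    2005: (13, 156, 276, 138),
    2008: (13, 123, 269, 178),
    2009: (13, 108, 246, 216),
    2010: (13, 107, 226, 237),
    2011: (13, 93, 220, 257),  # pre-fire
    2021: (13, 91, 111, 368),
}

AREA_LEDGER_2011_POST_FIRE: tuple[float, float, float, float] = (13, 93, 162, 315)

# Pooled survey densities: (year, species) ->
#   (cones/m2 available, kJ/m2 available, cones/m2 consumed, kJ/m2 consumed).
DENSITIES: dict[tuple[int, Species], tuple[float, float, float, float]] = {
    (2008, Species.SITKA_SPRUCE): (0.48, 2.25, 0.00, 0.00),
    (2008, Species.LODGEPOLE_PINE): (3.70, 21.84, 0.53, 3.13),
    (2009, Species.SITKA_SPRUCE): (0.02, 0.09, 0.00, 0.00),
    (2009, Species.LODGEPOLE_PINE): (3.37, 19.89, 0.71, 4.19),
    (2010, Species.SITKA_SPRUCE): (5.30, 24.84, 0.30, 1.41),
    (2010, Species.LODGEPOLE_PINE): (1.42, 8.38, 0.20, 1.18),
    (2011, Species.SITKA_SPRUCE): (2.12, 9.93, 0.14, 0.66),
    (2011, Species.LODGEPOLE_PINE): (1.35, 7.97, 0.37, 2.18),
    (2021, Species.SITKA_SPRUCE): (4.02, 18.83, 0.08, 0.37),
    (2021, Species.LODGEPOLE_PINE): (0.63, 3.33, 0.04, 0.21),
}

# Squirrel-occupied mature area by species and survey year, hectares.
# In 2021 positive squirrel signs were observed in every surveyed stand,
# so the occupied area equals the full mature area of each species.
OCCUPIED_AREAS_HA: dict[tuple[int, Species], float] = {
    (2008, Species.SITKA_SPRUCE): 0.0,
    (2008, Species.LODGEPOLE_PINE): 74.0,
    (2009, Species.SITKA_SPRUCE): 0.0,
    (2009, Species.LODGEPOLE_PINE): 104.0,
    (2010, Species.SITKA_SPRUCE): 36.0,
    (2010, Species.LODGEPOLE_PINE): 119.0,
    (2011, Species.SITKA_SPRUCE): 64.0,
    (2011, Species.LODGEPOLE_PINE): 126.0,
    (2021, Species.SITKA_SPRUCE): 91.0,
    (2021, Species.LODGEPOLE_PINE): 111.0,
}

# 2021 survey raw totals: 33 transects of 50 m x 1 m (1650 m2).
SURVEY_2021 = {
    "n_transects": 33,
    "transect_length_m": 50.0,
    "transect_width_m": 1.0,
    "sitka_total": 5599,
    "sitka_consumed": 136,
    "lodgepole_total": 1032,
    "lodgepole_consumed": 63,
    # cone measurement sample sizes and means
    "sitka_measured": 351,  # 136 consumed + 215 unconsumed, mean length 48.1 mm
    "sitka_length_mean_mm": 48.1,
    "sitka_scale_subsample": 110,
    "sitka_mean_scales": 117.0,
    "lodgepole_measured": 179,
    "lodgepole_length_mean_mm": 42.8,
}


def _year_stands(year: int) -> list[StandSnapshot]:
    broadleaf, sitka, lodgepole, unsuitable = AREA_LEDGER[year]
    occ_ss = OCCUPIED_AREAS_HA.get((year, Species.SITKA_SPRUCE), 0.0)
    occ_lp = OCCUPIED_AREAS_HA.get((year, Species.LODGEPOLE_PINE), 0.0)

    def conifer(stand_id: str, species: Species, area: float, occupied: bool) -> StandSnapshot:
        return StandSnapshot(
            stand_id=stand_id,
            year=year,
            species=species,
            planting_year=PLANTING_YEAR,
            status=StandStatus.MATURE,
            area_ha=area,
            occupied=occupied,
        )

    stands = [
        StandSnapshot(
            stand_id="nr-broadleaf",
            year=year,
            species=Species.BROADLEAF,
            status=StandStatus.BROADLEAF_RESERVE,
            area_ha=broadleaf,
        )
    ]
    for species, total, occ, tag in (
        (Species.SITKA_SPRUCE, sitka, occ_ss, "ss"),
        (Species.LODGEPOLE_PINE, lodgepole, occ_lp, "lp"),
    ):
        if occ <= 0:
            stands.append(conifer(f"{tag}-main", species, total, False))
        elif occ >= total:
            stands.append(conifer(f"{tag}-main", species, total, True))
        else:
            stands.append(conifer(f"{tag}-occ", species, occ, True))
            stands.append(conifer(f"{tag}-rest", species, total - occ, False))
    stands.append(
        StandSnapshot(
            stand_id="unsuitable",
            year=year,
            species=Species.OTHER,
            status=StandStatus.BARE_OR_FELLED,
            area_ha=unsuitable,
        )
    )
    return stands


def stand_snapshots() -> list[StandSnapshot]:
    """Stand ledger for all snapshot years (2011 in its pre-fire state)."""
    out: list[StandSnapshot] = []
    for year in sorted(AREA_LEDGER):
        out.extend(_year_stands(year))
    return out


def stand_snapshots_2011_post_fire() -> list[StandSnapshot]:
    """The 2011 ledger after the April fire burned 58 ha of lodgepole pine."""
    broadleaf, sitka, lodgepole, bare = AREA_LEDGER_2011_POST_FIRE
    year = 2011
    return [
        StandSnapshot(
            stand_id="nr-broadleaf",
            year=year,
            species=Species.BROADLEAF,
            status=StandStatus.BROADLEAF_RESERVE,
            area_ha=broadleaf,
        ),
        StandSnapshot(
            stand_id="ss-main",
            year=year,
            species=Species.SITKA_SPRUCE,
            planting_year=PLANTING_YEAR,
            status=StandStatus.MATURE,
            area_ha=sitka,
        ),
        StandSnapshot(
            stand_id="lp-main",
            year=year,
            species=Species.LODGEPOLE_PINE,
            planting_year=PLANTING_YEAR,
            status=StandStatus.MATURE,
            area_ha=lodgepole,
        ),
        StandSnapshot(
            stand_id="lp-burned",
            year=year,
            species=Species.LODGEPOLE_PINE,
            planting_year=PLANTING_YEAR,
            status=StandStatus.BURNED,
            area_ha=58.0,
        ),
        StandSnapshot(
            stand_id="unsuitable",
            year=year,
            species=Species.OTHER,
            status=StandStatus.BARE_OR_FELLED,
            area_ha=bare - 58.0,
        ),
    ]


def published_densities() -> list[EnergyDensity]:
    """The pooled per-m2 density table for all survey years."""
    out = []
    for (year, species), (ca, ea, cc, ec) in sorted(
        DENSITIES.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        out.append(
            EnergyDensity(
                species=species,
                year=year,
                cones_per_m2_available=ca,
                cones_per_m2_consumed=cc,
                energy_per_m2_available_kJ=ea,
                energy_per_m2_consumed_kJ=ec,
            )
        )
    return out
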