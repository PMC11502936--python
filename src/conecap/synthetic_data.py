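"""Synthetic feeding-survey generator and the packaged Derryclare fixture.

The generator emulates the statistical structure the analysis assumes:
per-transect cone counts with mean ``density x strip area``, drawn Poisson
or (by default) negative binomial — cone crops on 50-m2 strips under
masting are overdispersed — with consumption thinning each count
binomially; and cone measurements with Gaussian lengths and a linear
scales-on-length relationship plus Gaussian noise.

Default design parameters mirror the 2021 Derryclare survey: 33 strips of
50 m x 1 m; Sitka spruce at 4.02 cones/m2 (2% consumed) with mean length
48.1 mm; lodgepole pine at 0.63 cones/m2 (6.3% consumed) with mean length
42.8 mm.

Seeding contract: one root seed per design. Two independent child streams
are spawned from it in a fixed order — stream 0 feeds transect counts,
stream 1 feeds cone measurements — and within the transect stream, draws
happen transect by transect, species in declaration order (Sitka spruce
then lodgepole pine), available count before consumed count. Identical
designs therefore produce identical tables on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import derryclare
from .cone_energy import EnergyDensity
from .survey_io import (
    AnalysisConfig,
    ConeMeasurement,
    Species,
    SpeciesParams,
    StandSnapshot,
    TransectRecord,
    default_species_params,
)

__all__ = [
    "SpeciesDesign",
    "SurveyDesign",
    "DerryclareFixture",
    "generate_transects",
    "generate_cone_measurements",
    "derryclare_fixture",
]


class SpeciesDesign(BaseModel):
    """True per-species parameters of a simulated survey."""

    model_config = ConfigDict(frozen=True)

    true_density_per_m2: float = Field(ge=0)
    consumed_fraction: float = Field(ge=0, le=1)
    length_mean_mm: float = Field(gt=5, lt=200)
    length_sd_mm: float = Field(gt=0)
    scales_per_mm_slope: float = Field(default=2.4, gt=0)
    scales_intercept: float = Field(default=1.56, ge=0)
    scale_noise_sd: float = Field(default=13.0, ge=0)


class SurveyDesign(BaseModel):
    """A full simulated survey: strip geometry, species truths, count model."""

    model_config = ConfigDict(frozen=True)

    year: int = 2021
    n_transects: int = Field(default=33, ge=1)
    transect_length_m: float = Field(default=50.0, gt=0)
    width_m: float = Field(default=1.0, gt=0)
    species: dict[Species, SpeciesDesign] = Field(
        default_factory=lambda: {
            Species.SITKA_SPRUCE: SpeciesDesign(
                true_density_per_m2=4.02,
                consumed_fraction=0.02,
                length_mean_mm=48.1,
                length_sd_mm=8.2,
            ),
            Species.LODGEPOLE_PINE: SpeciesDesign(
                true_density_per_m2=0.63,
                consumed_fraction=0.063,
                length_mean_mm=42.8,
                length_sd_mm=7.1,
            ),
        }
    )
    dispersion: Literal["poisson", "negative_binomial"] = "negative_binomial"
    nb_dispersion: float = Field(default=1.5, gt=0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SurveyDesign":
        if not self.species:
            raise ValueError("a survey design needs at least one species")
        return self

    @property
    def transect_area_m2(self) -> float:
        return self.transect_length_m * self.width_m

    def count_variance(self, species: Species) -> float:
        """Variance of one transect's available count under the design."""
        mu = self.species[species].true_density_per_m2 * self.transect_area_m2
        if self.dispersion == "poisson":
            return mu
        return mu + mu**2 / self.nb_dispersion

    def _streams(self) -> tuple[np.random.Generator, np.random.Generator]:
        children = np.random.SeedSequence(self.rng_seed).spawn(2)
        return np.random.default_rng(children[0]), np.random.default_rng(children[1])


def _species_order(design: SurveyDesign) -> list[Species]:
    order = [s for s in Species if s in design.species]
    extras = [s for s in design.species if s not in order]
    return order + extras


def generate_transects(design: SurveyDesign) -> list[TransectRecord]:
    """Draw one survey's transect count table.

    Each transect yields one record per designed species; available counts
    follow the configured count distribution with mean density x area and
    consumed counts are binomial thinnings, so consumed <= available by
    construction.
    """
    rng, _ = design._streams()
    area = design.transect_area_m2
    records: list[TransectRecord] = []
    for t in range(design.n_transects):
        for species in _species_order(design):
            sd = design.species[species]
            mu = sd.true_density_per_m2 * area
            if mu == 0:
                available = 0
            elif design.dispersion == "poisson":
                available = int(rng.poisson(mu))
            else:
                k = design.nb_dispersion
                available = int(rng.negative_binomial(k, k / (k + mu)))
            consumed = int(rng.binomial(available, sd.consumed_fraction)) if available else 0
            records.append(
                TransectRecord(
                    transect_id=f"T{t + 1:02d}",
                    year=design.year,
                    stand_id="synthetic",
                    species=species,
                    cones_total=available,
                    cones_consumed=consumed,
                    length_m=design.transect_length_m,
                    width_m=design.width_m,
                )
            )
    return records


def generate_cone_measurements(
    design: SurveyDesign, n: int, species: Species = Species.SITKA_SPRUCE
) -> list[ConeMeasurement]:
    """Draw ``n`` cone measurements for one species.

    Lengths are Gaussian, redrawn until they fall in the plausible
    (5, 200) mm range. Sitka spruce cones additionally get a scale count
    ``round(slope * length + intercept + noise)`` floored at zero.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if species not in design.species:
        raise ValueError(f"design has no parameters for {species.value}")
    sd = design.species[species]
    _, rng = design._streams()
    lengths = rng.normal(sd.length_mean_mm, sd.length_sd_mm, size=n)
    bad = (lengths <= 5.0) | (lengths >= 200.0)
    while bad.any():
        lengths[bad] = rng.normal(sd.length_mean_mm, sd.length_sd_mm, size=int(bad.sum()))
        bad = (lengths <= 5.0) | (lengths >= 200.0)
    scales: Optional[np.ndarray] = None
    if species is Species.SITKA_SPRUCE:
        noise = rng.normal(0.0, sd.scale_noise_sd, size=n) if sd.scale_noise_sd > 0 else 0.0
        raw = sd.scales_per_mm_slope * lengths + sd.scales_intercept + noise
        scales = np.maximum(np.rint(raw), 0).astype(int)
    return [
        ConeMeasurement(
            species=species,
            length_mm=float(lengths[i]),
            scale_count=None if scales is None else int(scales[i]),
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class DerryclareFixture:
    """The packaged Derryclare inputs, ready for the full pipeline.

    ``stands`` holds every snapshot year with 2011 in its pre-fire state
    (the state the 2011 feeding survey sampled); the post-fire 2011 ledger
    is carried separately because a calendar year keys at most one snapshot
    in the stand table.
    """

    transects: list[TransectRecord]
    cones: list[ConeMeasurement]
    stands: list[StandSnapshot]
    stands_2011_post_fire: list[StandSnapshot]
    densities: list[EnergyDensity]
    config: AnalysisConfig
    species_params: dict[Species, SpeciesParams]


def _spread(total: int, n: int) -> list[int]:
    """Split ``total`` into ``n`` near-equal non-negative integers."""
    base, extra = divmod(total, n)
    return [base + 1 if i < extra else base for i in range(n)]


def _fixture_transects() -> list[TransectRecord]:
    s = derryclare.SURVEY_2021
    n = s["n_transects"]
    records = []
    for species, stand_id, total_key, cons_key in (
        (Species.SITKA_SPRUCE, "ss-main", "sitka_total", "sitka_consumed"),
        (Species.LODGEPOLE_PINE, "lp-main", "lodgepole_total", "lodgepole_consumed"),
    ):
        totals = _spread(s[total_key], n)
        consumed = _spread(s[cons_key], n)
        for i in range(n):
            records.append(
                TransectRecord(
                    transect_id=f"T{i + 1:02d}",
                    year=2021,
                    stand_id=stand_id,
                    species=species,
                    cones_total=totals[i],
                    cones_consumed=consumed[i],
                    length_m=s["transect_length_m"],
                    width_m=s["transect_width_m"],
                )
            )
    return records


def _fixture_cones() -> list[ConeMeasurement]:
    """Deterministic cone measurements reproducing the published means.

    Symmetric offsets around each published mean make the sample means
    exact: the 110-cone Sitka spruce scale subsample has mean scale count
    exactly 117, the full 351-cone Sitka spruce sample has mean length
    exactly 48.1 mm, and the 179 lodgepole pine lengths average exactly
    42.8 mm.
    """
    s = derryclare.SURVEY_2021
    cones: list[ConeMeasurement] = []

    # Sitka spruce scale subsample: scales 117 +/- k, lengths collinear.
    slope = 2.4
    offsets = [k for pair in ((-k, k) for k in range(1, 56)) for k in pair]
    for k in offsets:
        cones.append(
            ConeMeasurement(
                species=Species.SITKA_SPRUCE,
                length_mm=s["sitka_length_mean_mm"] + k / slope,
                scale_count=int(s["sitka_mean_scales"]) + k,
            )
        )

    # Remaining Sitka spruce cones (no scale counts): 120 symmetric pairs
    # plus one at the mean; the first 136 are the consumed collection.
    rest: list[float] = [s["sitka_length_mean_mm"]]
    for j in range(1, 121):
        rest.extend(
            (s["sitka_length_mean_mm"] - j * 0.15, s["sitka_length_mean_mm"] + j * 0.15)
        )
    for i, length in enumerate(rest):
        cones.append(
            ConeMeasurement(
                species=Species.SITKA_SPRUCE,
                length_mm=length,
                consumed=i < s["sitka_consumed"],
            )
        )

    # Lodgepole pine: 89 symmetric pairs plus one at the mean.
    lp: list[float] = [s["lodgepole_length_mean_mm"]]
    for j in range(1, 90):
        lp.extend(
            (s["lodgepole_length_mean_mm"] - j * 0.09, s["lodgepole_length_mean_mm"] + j * 0.09)
        )
    for i, length in enumerate(lp):
        cones.append(
            ConeMeasurement(
                species=Species.LODGEPOLE_PINE,
                length_mm=length,
                consumed=i < s["lodgepole_consumed"],
            )
        )
    return cones


def derryclare_fixture() -> DerryclareFixture:
    """Deterministic packaged encoding of the Derryclare surveys.

    No randomness is involved: counts, areas and densities are the
    published values, and the cone tables are symmetric constructions
    whose means equal the published means exactly. Running the full
    pipeline on this fixture reproduces the published ledger, energy and
    capacity tables.
    """
    return DerryclareFixture(
        transects=_fixture_transects(),
        cones=_fixture_cones(),
        stands=derryclare.stand_snapshots(),
        stands_2011_post_fire=derryclare.stand_snapshots_2011_post_fire(),
        densities=derryclare.published_densities(),
        config=AnalysisConfig(),
        species_params=default_species_params(),
    )
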