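"""Seeds-per-cone estimation and per-m2 cone/energy densities.

The energy value of a cone is estimated per species:

* Sitka spruce — the number of scales on a cone equals the number of seeds
  it can hold, so the mean scale count of a measured subsample is the mean
  seeds per cone. A scales-on-length ordinary-least-squares regression is
  fitted alongside to document how well length predicts seed number.
* Lodgepole pine — scale counting is unreliable, so seeds per cone are
  predicted from the mean cone length through a species-specific
  allometric equation.

Energy per cone is seeds x seed energy (0.04 kJ for a Sitka spruce seed,
0.098 kJ for a lodgepole pine seed), carried unrounded through the
pipeline. Cone densities are pooled as total counts over total surveyed
area, which makes the pooled density the area-weighted mean of
per-transect densities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats

from .survey_io import ConeMeasurement, Species, SpeciesParams, TransectRecord, _collect, _open_rows

__all__ = [
    "RegressionFit",
    "EnergyDensity",
    "DegenerateFitError",
    "fit_scale_length_regression",
    "seeds_per_cone",
    "energy_per_cone",
    "density_per_m2",
    "energy_density",
    "energy_density_table",
    "write_energy_densities",
    "read_energy_densities",
]


class DegenerateFitError(ValueError):
    """Raised when a regression cannot be identified (e.g. constant x)."""


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit of scale (= seed) counts on cone length.

    ``mean_seeds``/``se_mean_seeds`` summarise the raw scale counts and are
    what the energy calculation consumes; the slope documents the
    length-seeds relationship itself.
    """

    slope: float  # seeds per mm
    intercept: float  # seeds
    r: float
    r_squared: float
    n: int
    mean_seeds: float
    se_mean_seeds: float
    slope_se: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("a regression fit needs at least 3 points")
        if abs(self.r_squared - self.r**2) > 1e-9:
            raise ValueError("r_squared must equal r**2")


class EnergyDensity(BaseModel):
    """Per-species, per-year cone and energy densities (per m2)."""

    model_config = ConfigDict(frozen=True)

    species: Species
    year: int
    cones_per_m2_available: float = Field(ge=0)
    cones_per_m2_consumed: float = Field(ge=0)
    energy_per_m2_available_kJ: float = Field(ge=0)
    energy_per_m2_consumed_kJ: float = Field(ge=0)

    @model_validator(mode="after")
    def _check(self) -> "EnergyDensity":
        if self.cones_per_m2_consumed > self.cones_per_m2_available + 1e-9:
            raise ValueError("consumed cone density exceeds available cone density")
        if self.energy_per_m2_consumed_kJ > self.energy_per_m2_available_kJ + 1e-9:
            raise ValueError("consumed energy density exceeds available energy density")
        return self


def fit_scale_length_regression(measurements: Sequence[ConeMeasurement]) -> RegressionFit:
    """OLS regression of scale counts on cone length for Sitka spruce.

    Only measurements carrying a ``scale_count`` enter the fit; at least
    three are required, and the lengths must not all be identical.
    """
    usable = [m for m in measurements if m.scale_count is not None]
    if len(usable) < 3:
        raise ValueError(f"need at least 3 measurements with scale counts, got {len(usable)}")
    lengths = np.array([m.length_mm for m in usable], dtype=float)
    scales = np.array([m.scale_count for m in usable], dtype=float)
    if np.ptp(lengths) == 0:
        raise DegenerateFitError("all cone lengths identical; slope is not identifiable")
    fit = stats.linregress(lengths, scales)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
        n=len(usable),
        mean_seeds=float(np.mean(scales)),
        se_mean_seeds=float(stats.sem(scales)),
        slope_se=float(fit.stderr),
    )


def seeds_per_cone(
    species: Species,
    summary: Union[RegressionFit, float],
    params: SpeciesParams,
) -> float:
    """Seeds in the average cone of ``species``.

    For Sitka spruce, ``summary`` is a :class:`RegressionFit` (or a bare
    mean scale count) and seeds are scales x seeds_per_scale. For lodgepole
    pine, ``summary`` is the mean cone length in mm, mapped through the
    configured allometric equation.
    """
    if species is Species.SITKA_SPRUCE:
        mean_scales = summary.mean_seeds if isinstance(summary, RegressionFit) else float(summary)
        if mean_scales <= 0:
            raise ValueError(f"mean scale count must be positive, got {mean_scales}")
        return mean_scales * params.seeds_per_scale
    if species is Species.LODGEPOLE_PINE:
        if isinstance(summary, RegressionFit):
            raise TypeError("lodgepole pine seeds are predicted from mean length, not a scale fit")
        if params.allometric is None:
            raise ValueError("lodgepole pine requires allometric coefficients in SpeciesParams")
        return params.allometric.seeds(float(summary))
    raise ValueError(f"no seeds-per-cone rule for species {species.value}")


def energy_per_cone(seeds: float, seed_energy_kJ: float) -> float:
    """Energy content (kJ) of a cone holding ``seeds`` seeds."""
    if seeds <= 0 or seed_energy_kJ <= 0:
        raise ValueError("seeds and seed energy must both be positive")
    return seeds * seed_energy_kJ


def density_per_m2(
    records: Sequence[TransectRecord],
    which: Literal["available", "consumed"] = "available",
) -> float:
    """Pooled cone density: total counts over total surveyed area.

    ``which`` selects all counted cones ("available") or only
    squirrel-stripped ones ("consumed"). All records must belong to one
    species and one survey year; pooling across species or years would
    average incommensurable crops.
    """
    if not records:
        raise ValueError("cannot compute a density from an empty record list")
    keys = {(r.species, r.year) for r in records}
    if len(keys) > 1:
        raise ValueError(f"records span multiple species/years: {sorted((s.value, y) for s, y in keys)}")
    if which not in ("available", "consumed"):
        raise ValueError(f"which must be 'available' or 'consumed', got {which!r}")
    counts = sum(r.cones_total if which == "available" else r.cones_consumed for r in records)
    area = sum(r.area_m2 for r in records)
    if area <= 0:
        raise ValueError("total surveyed area must be positive")
    return counts / area


def energy_density(density: float, energy_per_cone_kJ: float) -> float:
    """Energy density (kJ/m2) = cone density x energy per cone."""
    if density < 0 or energy_per_cone_kJ < 0:
        raise ValueError("density and per-cone energy must be non-negative")
    return density * energy_per_cone_kJ


def energy_density_table(
    transects: Iterable[TransectRecord],
    energy_per_cone_kJ: Mapping[Species, float],
) -> list[EnergyDensity]:
    """Per-species, per-year densities from raw transect counts.

    Every (species, year) group present in ``transects`` must have a
    per-cone energy entry.
    """
    groups: dict[tuple[Species, int], list[TransectRecord]] = {}
    for r in transects:
        groups.setdefault((r.species, r.year), []).append(r)
    out = []
    for (species, year), records in sorted(groups.items(), key=lambda kv: (kv[0][1], kv[0][0].value)):
        if species not in energy_per_cone_kJ:
            raise ValueError(f"no per-cone energy supplied for {species.value}")
        e_cone = energy_per_cone_kJ[species]
        avail = density_per_m2(records, "available")
        cons = density_per_m2(records, "consumed")
        out.append(
            EnergyDensity(
                species=species,
                year=year,
                cones_per_m2_available=avail,
                cones_per_m2_consumed=cons,
                energy_per_m2_available_kJ=energy_density(avail, e_cone),
                energy_per_m2_consumed_kJ=energy_density(cons, e_cone),
            )
        )
    return out


_DENSITY_COLUMNS = [
    "species",
    "year",
    "cones_per_m2_available",
    "cones_per_m2_consumed",
    "energy_per_m2_available_kJ",
    "energy_per_m2_consumed_kJ",
]


def write_energy_densities(densities: Sequence[EnergyDensity], path: Union[str, Path]) -> None:
    """Write the per-species, per-year density table as CSV.

    Values are written at full precision; the conventional 2-dp display
    rounding is applied only when tables are rendered for people.
    """
    if not densities:
        raise ValueError("cannot write an empty density table")
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_DENSITY_COLUMNS)
        for d in densities:
            writer.writerow(
                [
                    d.species.value,
                    d.year,
                    repr(d.cones_per_m2_available),
                    repr(d.cones_per_m2_consumed),
                    repr(d.energy_per_m2_available_kJ),
                    repr(d.energy_per_m2_consumed_kJ),
                ]
            )


def read_energy_densities(path: Union[str, Path]) -> list[EnergyDensity]:
    """Read a density table written by :func:`write_energy_densities`."""
    rows, _ = _open_rows(path, _DENSITY_COLUMNS)

    def build(row: dict) -> EnergyDensity:
        return EnergyDensity(
            species=Species(row["species"]),
            year=int(row["year"]),
            cones_per_m2_available=float(row["cones_per_m2_available"]),
            cones_per_m2_consumed=float(row["cones_per_m2_consumed"]),
            energy_per_m2_available_kJ=float(row["energy_per_m2_available_kJ"]),
            energy_per_m2_consumed_kJ=float(row["energy_per_m2_consumed_kJ"]),
        )

    return _collect(path, rows, build)
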