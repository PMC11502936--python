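"""Domain types, validated CSV readers/writers and unit conventions.

Everything downstream of the field work flows through the three tables
defined here: transect cone counts (``transects.csv``), individual cone
measurements (``cones.csv``) and the stand-area ledger (``stands.csv``).
Areas are stored in hectares throughout; conversion to square metres is
always an exact factor of 10,000. CSV files are comma-separated UTF-8 with
a mandatory header row and a decimal point.

Species names form a closed vocabulary: an unknown species in an input file
is an error, never a silent skip, because silently dropped rows would
dilute every density computed later.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

M2_PER_HA = 10_000  # exact by convention

__all__ = [
    "Species",
    "CONIFERS",
    "StandStatus",
    "TransectRecord",
    "ConeMeasurement",
    "StandSnapshot",
    "AllometricModel",
    "SpeciesParams",
    "AnalysisConfig",
    "CapacityReportRow",
    "SurveyIOError",
    "SchemaError",
    "RowValidationError",
    "read_transects",
    "read_cone_measurements",
    "read_stand_ledger",
    "write_transects",
    "write_cone_measurements",
    "write_stand_ledger",
    "write_report",
    "read_report",
    "load_config",
    "default_species_params",
]


class Species(str, enum.Enum):
    """Tree species vocabulary of the study forest."""

    SITKA_SPRUCE = "sitka_spruce"
    LODGEPOLE_PINE = "lodgepole_pine"
    BROADLEAF = "broadleaf"
    OTHER = "other"


#: The two cone-bearing conifers that squirrel feeding surveys record.
CONIFERS = (Species.SITKA_SPRUCE, Species.LODGEPOLE_PINE)


class StandStatus(str, enum.Enum):
    MATURE = "mature"
    IMMATURE = "immature"
    BARE_OR_FELLED = "bare_or_felled"
    BURNED = "burned"
    BROADLEAF_RESERVE = "broadleaf_reserve"


class SurveyIOError(Exception):
    """Base class for table reading/writing failures."""


class SchemaError(SurveyIOError):
    """A required column is missing or the header is malformed."""


class RowValidationError(SurveyIOError):
    """One or more rows violate a typed invariant.

    The message names each offending row by its 1-based line number in the
    source file so the row can be located and fixed.
    """


class TransectRecord(BaseModel):
    """Cone counts for one species on one surveyed strip.

    A transect is a ground strip (default 50 m x 1 m) walked through a
    mature stand; every cone found is identified to species and scored as
    consumed (stripped by a squirrel) or still intact.
    """

    model_config = ConfigDict(frozen=True)

    transect_id: str
    year: int
    stand_id: str
    species: Species
    cones_total: int = Field(ge=0)
    cones_consumed: int = Field(ge=0)
    length_m: float = Field(default=50.0, gt=0)
    width_m: float = Field(default=1.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "TransectRecord":
        if self.species not in CONIFERS:
            raise ValueError(f"transect records must be conifer species, got {self.species.value}")
        if self.cones_consumed > self.cones_total:
            raise ValueError(
                f"cones_consumed ({self.cones_consumed}) exceeds cones_total ({self.cones_total})"
            )
        return self

    @property
    def area_m2(self) -> float:
        return self.length_m * self.width_m


class ConeMeasurement(BaseModel):
    """A single cone's length (mm) and, for Sitka spruce, its scale count."""

    model_config = ConfigDict(frozen=True)

    species: Species
    length_mm: float
    scale_count: Optional[int] = Field(default=None, ge=0)
    consumed: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ConeMeasurement":
        if not (5.0 < self.length_mm < 200.0):
            raise ValueError(f"cone length {self.length_mm} mm outside the plausible (5, 200) range")
        if self.scale_count is not None and self.species is not Species.SITKA_SPRUCE:
            raise ValueError("scale counts are only recorded for Sitka spruce cones")
        return self


class StandSnapshot(BaseModel):
    """One stand's species, status, area and occupancy in one snapshot year."""

    model_config = ConfigDict(frozen=True)

    stand_id: str
    year: int
    species: Species
    planting_year: Optional[int] = None
    status: StandStatus
    area_ha: float = Field(ge=0)
    occupied: bool = False

    @model_validator(mode="after")
    def _check(self) -> "StandSnapshot":
        if self.status is StandStatus.MATURE and self.species not in CONIFERS:
            raise ValueError("only conifer stands can be mature cone producers")
        return self

    @property
    def age(self) -> Optional[int]:
        if self.planting_year is None:
            return None
        return self.year - self.planting_year


class AllometricModel(BaseModel):
    """Seeds-per-cone as a function of cone length (mm).

    Currently a linear family ``seeds = slope * length + intercept``; the
    default lodgepole pine calibration passes through the origin so that
    positive lengths always yield positive seed counts.
    """

    model_config = ConfigDict(frozen=True)

    family: str = "linear"
    slope: float = Field(gt=0)
    intercept: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "AllometricModel":
        if self.family != "linear":
            raise ValueError(f"unknown allometric family {self.family!r}")
        return self

    def seeds(self, length_mm: float) -> float:
        if length_mm <= 0:
            raise ValueError(f"cone length must be positive, got {length_mm}")
        return self.slope * length_mm + self.intercept


# Lodgepole pine seeds-per-cone calibration: linear through the origin,
# anchored at 54 seeds for the 42.8 mm mean cone.
DEFAULT_LODGEPOLE_SLOPE = 54.0 / 42.8


class SpeciesParams(BaseModel):
    """Per-species energetics: seed energy and the seeds-per-cone rule."""

    model_config = ConfigDict(frozen=True)

    species: Species
    seed_energy_kJ: float = Field(gt=0)
    allometric: Optional[AllometricModel] = None
    #: Seeds realised per cone scale (Sitka spruce scale-count method).
    seeds_per_scale: float = Field(default=1.0, gt=0)


def default_species_params() -> dict[Species, SpeciesParams]:
    """Energetic defaults for the two surveyed conifers.

    Seed energy values are 0.04 kJ for a Sitka spruce seed and 0.098 kJ
    for a lodgepole pine seed.
    """
    return {
        Species.SITKA_SPRUCE: SpeciesParams(
            species=Species.SITKA_SPRUCE, seed_energy_kJ=0.04
        ),
        Species.LODGEPOLE_PINE: SpeciesParams(
            species=Species.LODGEPOLE_PINE,
            seed_energy_kJ=0.098,
            allometric=AllometricModel(slope=DEFAULT_LODGEPOLE_SLOPE),
        ),
    }


class AnalysisConfig(BaseModel):
    """Tunable parameters of the capacity analysis.

    ``daily_requirement_low_kJ``/``daily_requirement_high_kJ`` bracket a red
    squirrel's daily energy need (400-700 kJ/day). ``horizon_days`` is the
    period over which one season's cone crop is assumed to feed the
    population (365 days). ``area_density_per_ha`` is the literature density
    used by the purely area-based estimate (0.32 squirrels/ha in a
    comparable spruce/pine forest). ``maturity_age_years`` is the stand age
    from which a usable cone crop is produced (25 years).
    """

    model_config = ConfigDict(frozen=True)

    daily_requirement_low_kJ: float = Field(default=400.0, gt=0)
    daily_requirement_high_kJ: float = Field(default=700.0, gt=0)
    horizon_days: int = Field(default=365, gt=0)
    area_density_per_ha: float = Field(default=0.32, gt=0)
    maturity_age_years: int = Field(default=25, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        if self.daily_requirement_low_kJ >= self.daily_requirement_high_kJ:
            raise ValueError("daily_requirement_low_kJ must be below daily_requirement_high_kJ")
        return self


@dataclass(frozen=True)
class CapacityReportRow:
    """One year of the capacity report (the machine twin of the results table).

    ``label`` distinguishes sub-year snapshots such as the pre- and
    post-fire states of a single calendar year. Feeding-survey fields are
    ``None`` for years with a ledger entry but no survey.
    """

    label: str
    year: int
    mature_ha: float
    area_capacity: int
    fs_capacity_low: Optional[int] = None
    fs_capacity_high: Optional[int] = None
    fs_actual_low: Optional[int] = None
    fs_actual_high: Optional[int] = None


# ---------------------------------------------------------------------------
# CSV plumbing

def _open_rows(path: Union[str, Path], required: Sequence[str]) -> tuple[list[dict], list[str]]:
    """Read CSV rows, returning (rows-with-line-numbers, comment lines)."""
    path = Path(path)
    if not path.exists():
        raise SurveyIOError(f"no such file: {path}")
    comments: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for line in lines:
        if line.startswith("#"):
            comments.append(line)
            body_start += 1
        else:
            break
    reader = csv.DictReader(lines[body_start:])
    if reader.fieldnames is None:
        raise SchemaError(f"{path}: empty file, header row is mandatory")
    missing = [c for c in required if c not in reader.fieldnames]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    rows = []
    for i, row in enumerate(reader):
        row["__line__"] = body_start + i + 2  # 1-based, after header
        rows.append(row)
    return rows, comments


def _collect(path: Union[str, Path], rows: Iterable[dict], build) -> list:
    """Build records row by row, accumulating per-line validation errors."""
    out, errors = [], []
    for row in rows:
        line = row.pop("__line__")
        try:
            out.append(build(row))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise RowValidationError(f"{path}: {len(errors)} invalid row(s):\n" + "\n".join(errors))
    return out


def _opt(value: Optional[str]) -> Optional[str]:
    return None if value is None or value.strip() == "" else value.strip()


TRANSECT_COLUMNS = ["transect_id", "year", "stand_id", "species", "cones_total", "cones_consumed"]
CONE_COLUMNS = ["species", "length_mm"]
STAND_COLUMNS = ["stand_id", "year", "species", "planting_year", "status", "area_ha", "occupied"]


def read_transects(path: Union[str, Path]) -> list[TransectRecord]:
    """Read and validate a transect count table.

    Optional ``length_m``/``width_m`` columns (or blank cells) fall back to
    the standard 50 m x 1 m strip.
    """
    rows, _ = _open_rows(path, TRANSECT_COLUMNS)

    def build(row: dict) -> TransectRecord:
        return TransectRecord(
            transect_id=row["transect_id"],
            year=int(row["year"]),
            stand_id=row["stand_id"],
            species=Species(row["species"]),
            cones_total=int(row["cones_total"]),
            cones_consumed=int(row["cones_consumed"]),
            length_m=float(_opt(row.get("length_m")) or 50.0),
            width_m=float(_opt(row.get("width_m")) or 1.0),
        )

    return _collect(path, rows, build)


def read_cone_measurements(path: Union[str, Path]) -> list[ConeMeasurement]:
    """Read and validate a cone measurement table."""
    rows, _ = _open_rows(path, CONE_COLUMNS)

    def build(row: dict) -> ConeMeasurement:
        scale = _opt(row.get("scale_count"))
        consumed = _opt(row.get("consumed")) or "false"
        return ConeMeasurement(
            species=Species(row["species"]),
            length_mm=float(row["length_mm"]),
            scale_count=None if scale is None else int(scale),
            consumed=consumed.lower() in ("1", "true", "yes"),
        )

    return _collect(path, rows, build)


def read_stand_ledger(path: Union[str, Path]) -> list[StandSnapshot]:
    """Read and validate a stand-area ledger.

    A leading comment of the form ``# forest_total_ha: 583`` declares the
    fixed extent of the forest; when present, the stand areas of every
    snapshot year must sum to it within 0.5 ha (stands may change class but
    the forest does not change size).
    """
    rows, comments = _open_rows(path, STAND_COLUMNS)

    def build(row: dict) -> StandSnapshot:
        planting = _opt(row.get("planting_year"))
        return StandSnapshot(
            stand_id=row["stand_id"],
            year=int(row["year"]),
            species=Species(row["species"]),
            planting_year=None if planting is None else int(planting),
            status=StandStatus(row["status"]),
            area_ha=float(row["area_ha"]),
            occupied=(_opt(row.get("occupied")) or "false").lower() in ("1", "true", "yes"),
        )

    snapshots = _collect(path, rows, build)

    declared = None
    for line in comments:
        text = line.lstrip("#").strip()
        if text.startswith("forest_total_ha"):
            declared = float(text.split(":", 1)[1])
    if declared is not None:
        totals: dict[int, float] = {}
        for s in snapshots:
            totals[s.year] = totals.get(s.year, 0.0) + s.area_ha
        for year, total in sorted(totals.items()):
            if abs(total - declared) > 0.5:
                raise RowValidationError(
                    f"{path}: year {year} stand areas sum to {total:.1f} ha, "
                    f"declared forest total is {declared:.1f} ha"
                )
    return snapshots


def write_transects(records: Sequence[TransectRecord], path: Union[str, Path]) -> None:
    """Write transect records in the ``transects.csv`` schema."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(TRANSECT_COLUMNS + ["length_m", "width_m"])
        for r in records:
            writer.writerow(
                [
                    r.transect_id,
                    r.year,
                    r.stand_id,
                    r.species.value,
                    r.cones_total,
                    r.cones_consumed,
                    repr(r.length_m),
                    repr(r.width_m),
                ]
            )


def write_cone_measurements(cones: Sequence[ConeMeasurement], path: Union[str, Path]) -> None:
    """Write cone measurements in the ``cones.csv`` schema."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["species", "length_mm", "scale_count", "consumed"])
        for c in cones:
            writer.writerow(
                [
                    c.species.value,
                    repr(c.length_mm),
                    "" if c.scale_count is None else c.scale_count,
                    str(c.consumed).lower(),
                ]
            )


def write_stand_ledger(
    stands: Sequence[StandSnapshot],
    path: Union[str, Path],
    forest_total_ha: Optional[float] = None,
) -> None:
    """Write stand snapshots in the ``stands.csv`` schema.

    When ``forest_total_ha`` is given it is recorded as a header comment
    and re-checked on read.
    """
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        if forest_total_ha is not None:
            fh.write(f"# forest_total_ha: {forest_total_ha}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(STAND_COLUMNS)
        for s in stands:
            writer.writerow(
                [
                    s.stand_id,
                    s.year,
                    s.species.value,
                    "" if s.planting_year is None else s.planting_year,
                    s.status.value,
                    repr(s.area_ha),
                    str(s.occupied).lower(),
                ]
            )


# Capacity report: densities at 2 dp, energies at whole kJ, squirrels whole.
_REPORT_COLUMNS = [
    "label",
    "year",
    "mature_ha",
    "area_capacity",
    "fs_capacity_low",
    "fs_capacity_high",
    "fs_actual_low",
    "fs_actual_high",
]


def write_report(results: Sequence[CapacityReportRow], path: Union[str, Path]) -> None:
    """Write the per-year capacity report as CSV.

    The format is canonical (fixed column order, one decimal place for
    hectares, empty cells for missing survey years) so that a read/rewrite
    cycle is byte-identical.
    """
    if not results:
        raise SurveyIOError("cannot write an empty report")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_REPORT_COLUMNS)
        for row in results:
            writer.writerow(
                [
                    row.label,
                    row.year,
                    f"{row.mature_ha:.1f}",
                    row.area_capacity,
                    "" if row.fs_capacity_low is None else row.fs_capacity_low,
                    "" if row.fs_capacity_high is None else row.fs_capacity_high,
                    "" if row.fs_actual_low is None else row.fs_actual_low,
                    "" if row.fs_actual_high is None else row.fs_actual_high,
                ]
            )


def read_report(path: Union[str, Path]) -> list[CapacityReportRow]:
    """Read back a capacity report written by :func:`write_report`."""
    rows, _ = _open_rows(path, _REPORT_COLUMNS)

    def build(row: dict) -> CapacityReportRow:
        def opt_int(key: str) -> Optional[int]:
            v = _opt(row.get(key))
            return None if v is None else int(v)

        return CapacityReportRow(
            label=row["label"],
            year=int(row["year"]),
            mature_ha=float(row["mature_ha"]),
            area_capacity=int(row["area_capacity"]),
            fs_capacity_low=opt_int("fs_capacity_low"),
            fs_capacity_high=opt_int("fs_capacity_high"),
            fs_actual_low=opt_int("fs_actual_low"),
            fs_actual_high=opt_int("fs_actual_high"),
        )

    return _collect(path, rows, build)


def load_config(
    path: Optional[Union[str, Path]] = None,
) -> tuple[AnalysisConfig, dict[Species, SpeciesParams]]:
    """Load analysis and species parameters from YAML, with built-in defaults.

    The YAML file has two optional top-level keys, ``analysis`` and
    ``species``; anything omitted keeps its default. Example::

        analysis:
          horizon_days: 365
        species:
          lodgepole_pine:
            seed_energy_kJ: 0.098
            allometric: {family: linear, slope: 1.2617, intercept: 0.0}
    """
    config = AnalysisConfig()
    species_params = default_species_params()
    if path is None:
        return config, species_params
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "analysis" in raw and raw["analysis"]:
        config = AnalysisConfig(**raw["analysis"])
    for name, fields in (raw.get("species") or {}).items():
        species = Species(name)
        fields = dict(fields)
        if "allometric" in fields and fields["allometric"] is not None:
            fields["allometric"] = AllometricModel(**fields["allometric"])
        base = species_params.get(species)
        if base is not None:
            merged = base.model_dump()
            merged.update(fields)
            merged["species"] = species
            if isinstance(merged.get("allometric"), dict):
                merged["allometric"] = AllometricModel(**merged["allometric"])
            species_params[species] = SpeciesParams(**merged)
        else:
            species_params[species] = SpeciesParams(species=species, **fields)
    return config, species_params


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    This is the rounding convention of every published squirrel count in
    the study tables (e.g. 138.24 -> 138, 81.53 -> 82).
    """
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)
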