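"""Validated CSV readers/writers and domain-type invariants."""

import pytest
from pydantic import ValidationError

from conecap import survey_io
from conecap.survey_io import (
    AnalysisConfig,
    CapacityReportRow,
    ConeMeasurement,
    RowValidationError,
    SchemaError,
    Species,
    StandSnapshot,
    StandStatus,
    TransectRecord,
)


class TestTransectIO:
    def test_fixture_round_trip_preserves_counts(self, fixture, tmp_path):
        sitka = [t for t in fixture.transects if t.species is Species.SITKA_SPRUCE]
        path = tmp_path / "transects.csv"
        survey_io.write_transects(sitka, path)
        back = survey_io.read_transects(path)
        assert len(back) == 33
        assert sum(t.cones_total for t in back) == 5599
        assert sum(t.cones_consumed for t in back) == 136
        assert back == sitka

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("transect_id,year,stand_id,species,cones_total,cones_consumed\n")
        assert survey_io.read_transects(path) == []

    def test_consumed_exceeding_total_names_the_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "transect_id,year,stand_id,species,cones_total,cones_consumed\n"
            "T01,2021,s1,sitka_spruce,10,2\n"
            "T02,2021,s1,sitka_spruce,3,5\n"
        )
        with pytest.raises(RowValidationError, match="line 3"):
            survey_io.read_transects(path)

    def test_missing_column_is_a_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("transect_id,year,stand_id,species,cones_total\nT01,2021,s1,sitka_spruce,1\n")
        with pytest.raises(SchemaError, match="cones_consumed"):
            survey_io.read_transects(path)

    def test_unknown_species_is_rejected_not_skipped(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "transect_id,year,stand_id,species,cones_total,cones_consumed\n"
            "T01,2021,s1,norway_spruce,10,2\n"
        )
        with pytest.raises(RowValidationError):
            survey_io.read_transects(path)

    def test_blank_geometry_defaults_to_standard_strip(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "transect_id,year,stand_id,species,cones_total,cones_consumed,length_m,width_m\n"
            "T01,2021,s1,sitka_spruce,10,2,,\n"
        )
        (rec,) = survey_io.read_transects(path)
        assert rec.area_m2 == 50.0


class TestStandLedgerIO:
    def test_fixture_ledger_round_trip(self, fixture, tmp_path):
        path = tmp_path / "stands.csv"
        survey_io.write_stand_ledger(fixture.stands, path, forest_total_ha=583.0)
        back = survey_io.read_stand_ledger(path)
        assert back == fixture.stands
        total_2005 = sum(s.area_ha for s in back if s.year == 2005)
        assert total_2005 == pytest.approx(583.0)

    def test_zero_area_stand_is_accepted(self, tmp_path):
        path = tmp_path / "stands.csv"
        path.write_text(
            "stand_id,year,species,planting_year,status,area_ha,occupied\n"
            "s1,2021,sitka_spruce,1965,mature,0,false\n"
        )
        (snap,) = survey_io.read_stand_ledger(path)
        assert snap.area_ha == 0.0

    def test_negative_area_is_rejected(self, tmp_path):
        path = tmp_path / "stands.csv"
        path.write_text(
            "stand_id,year,species,planting_year,status,area_ha,occupied\n"
            "s1,2021,sitka_spruce,1965,mature,-1,false\n"
        )
        with pytest.raises(RowValidationError):
            survey_io.read_stand_ledger(path)

    def test_declared_forest_total_is_enforced(self, tmp_path):
        path = tmp_path / "stands.csv"
        path.write_text(
            "# forest_total_ha: 100\n"
            "stand_id,year,species,planting_year,status,area_ha,occupied\n"
            "s1,2021,sitka_spruce,1965,mature,42,false\n"
        )
        with pytest.raises(RowValidationError, match="declared forest total"):
            survey_io.read_stand_ledger(path)


class TestReport:
    ROWS = [
        CapacityReportRow("2005", 2005, 432.0, 138),
        CapacityReportRow("2021", 2021, 202.0, 65, 82, 143, 2, 4),
    ]

    def test_round_trip_is_lossless(self, tmp_path):
        path = tmp_path / "capacity.csv"
        survey_io.write_report(self.ROWS, path)
        assert survey_io.read_report(path) == self.ROWS

    def test_rewrite_is_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        survey_io.write_report(self.ROWS, p1)
        survey_io.write_report(survey_io.read_report(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_report_is_an_error(self, tmp_path):
        with pytest.raises(survey_io.SurveyIOError):
            survey_io.write_report([], tmp_path / "x.csv")


class TestTypes:
    def test_transect_consumed_cannot_exceed_total(self):
        with pytest.raises(ValidationError):
            TransectRecord(
                transect_id="T",
                year=2021,
                stand_id="s",
                species=Species.SITKA_SPRUCE,
                cones_total=3,
                cones_consumed=5,
            )

    @pytest.mark.parametrize("length", [4.0, 250.0])
    def test_cone_length_outside_plausible_range(self, length):
        with pytest.raises(ValidationError):
            ConeMeasurement(species=Species.SITKA_SPRUCE, length_mm=length)

    def test_scale_counts_are_sitka_only(self):
        with pytest.raises(ValidationError):
            ConeMeasurement(species=Species.LODGEPOLE_PINE, length_mm=40, scale_count=50)

    def test_mature_stand_must_be_conifer(self):
        with pytest.raises(ValidationError):
            StandSnapshot(
                stand_id="s",
                year=2021,
                species=Species.BROADLEAF,
                status=StandStatus.MATURE,
                area_ha=10,
            )

    def test_config_requires_low_below_high(self):
        with pytest.raises(ValidationError):
            AnalysisConfig(daily_requirement_low_kJ=700, daily_requirement_high_kJ=400)


class TestConfig:
    def test_defaults(self):
        cfg, params = survey_io.load_config(None)
        assert cfg.daily_requirement_low_kJ == 400
        assert cfg.daily_requirement_high_kJ == 700
        assert cfg.horizon_days == 365
        assert cfg.area_density_per_ha == 0.32
        assert cfg.maturity_age_years == 25
        assert params[Species.SITKA_SPRUCE].seed_energy_kJ == 0.04
        assert params[Species.LODGEPOLE_PINE].seed_energy_kJ == 0.098
        assert params[Species.LODGEPOLE_PINE].allometric is not None

    def test_yaml_overrides_merge_with_defaults(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "analysis:\n  horizon_days: 180\n"
            "species:\n  lodgepole_pine:\n    seed_energy_kJ: 0.1\n"
        )
        cfg, params = survey_io.load_config(path)
        assert cfg.horizon_days == 180
        assert cfg.daily_requirement_low_kJ == 400
        assert params[Species.LODGEPOLE_PINE].seed_energy_kJ == 0.1
        # merged fields keep their defaults
        assert params[Species.LODGEPOLE_PINE].allometric.slope == pytest.approx(54.0 / 42.8)
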