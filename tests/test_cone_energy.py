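"""Seed allometry, regression fitting and density pooling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conecap import cone_energy
from conecap.cone_energy import (
    DegenerateFitError,
    EnergyDensity,
    density_per_m2,
    energy_density,
    energy_per_cone,
    fit_scale_length_regression,
    seeds_per_cone,
)
from conecap.survey_io import ConeMeasurement, Species, TransectRecord, default_species_params
from conecap.synthetic_data import SurveyDesign, generate_cone_measurements


def _cones(lengths, scales):
    return [
        ConeMeasurement(species=Species.SITKA_SPRUCE, length_mm=l, scale_count=s)
        for l, s in zip(lengths, scales)
    ]


class TestRegression:
    def test_perfect_line_recovered_exactly(self):
        lengths = [10.0, 20.0, 30.0, 40.0]
        fit = fit_scale_length_regression(_cones(lengths, [2 * l for l in lengths]))
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        # brute-force closed form: slope = cov(x,y)/var(x)
        rng = np.random.default_rng(7)
        x = rng.uniform(20, 80, size=50)
        y = 2.4 * x + 1.5 + rng.normal(0, 12, size=50)
        fit = fit_scale_length_regression(_cones(x, np.rint(np.abs(y)).astype(int)))
        yy = np.rint(np.abs(y))
        slope = np.sum((x - x.mean()) * (yy - yy.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = yy.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_recovers_true_slope_within_three_se(self):
        design = SurveyDesign(rng_seed=11)
        cones = generate_cone_measurements(design, 110, Species.SITKA_SPRUCE)
        fit = fit_scale_length_regression(cones)
        true_slope = design.species[Species.SITKA_SPRUCE].scales_per_mm_slope
        assert abs(fit.slope - true_slope) < 3 * fit.slope_se

    def test_constant_lengths_are_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_scale_length_regression(_cones([30.0] * 5, [70, 71, 72, 73, 74]))

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            fit_scale_length_regression(_cones([10.0, 20.0], [20, 40]))


class TestSeedsPerCone:
    def test_sitka_uses_mean_scale_count(self, fixture):
        params = default_species_params()
        sitka = [c for c in fixture.cones if c.scale_count is not None]
        fit = fit_scale_length_regression(sitka)
        assert seeds_per_cone(Species.SITKA_SPRUCE, fit, params[Species.SITKA_SPRUCE]) == 117.0

    def test_lodgepole_allometric_anchor_point(self):
        params = default_species_params()
        seeds = seeds_per_cone(Species.LODGEPOLE_PINE, 42.8, params[Species.LODGEPOLE_PINE])
        assert seeds == pytest.approx(54.0)

    def test_lodgepole_zero_length_is_an_error(self):
        params = default_species_params()
        with pytest.raises(ValueError):
            seeds_per_cone(Species.LODGEPOLE_PINE, 0.0, params[Species.LODGEPOLE_PINE])

    def test_lodgepole_without_allometric_is_a_configuration_error(self):
        from conecap.survey_io import SpeciesParams

        params = SpeciesParams(species=Species.LODGEPOLE_PINE, seed_energy_kJ=0.098)
        with pytest.raises(ValueError, match="allometric"):
            seeds_per_cone(Species.LODGEPOLE_PINE, 42.8, params)


class TestEnergyPerCone:
    @pytest.mark.parametrize(
        "seeds,energy,expected",
        [(117, 0.04, 4.68), (54, 0.098, 5.292), (1, 1, 1)],
    )
    def test_product(self, seeds, energy, expected):
        assert energy_per_cone(seeds, energy) == pytest.approx(expected)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            energy_per_cone(0, 0.04)


def _records(counts, consumed=None, species=Species.LODGEPOLE_PINE, year=2021, length=50.0):
    consumed = consumed or [0] * len(counts)
    return [
        TransectRecord(
            transect_id=f"T{i}",
            year=year,
            stand_id="s",
            species=species,
            cones_total=c,
            cones_consumed=k,
            length_m=length,
        )
        for i, (c, k) in enumerate(zip(counts, consumed))
    ]


class TestDensity:
    def test_2021_lodgepole_pooled_density(self, fixture):
        lp = [t for t in fixture.transects if t.species is Species.LODGEPOLE_PINE]
        assert round(density_per_m2(lp, "available"), 2) == 0.63  # 1032 cones / 1650 m2

    def test_2021_consumed_sitka_density(self, fixture):
        ss = [t for t in fixture.transects if t.species is Species.SITKA_SPRUCE]
        assert round(density_per_m2(ss, "consumed"), 2) == 0.08  # 136 / 1650

    def test_zero_counts_give_zero_density(self):
        assert density_per_m2(_records([0, 0, 0])) == 0.0

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            density_per_m2([])

    def test_mixed_species_rejected(self):
        records = _records([1], species=Species.SITKA_SPRUCE) + _records([1])
        with pytest.raises(ValueError, match="multiple"):
            density_per_m2(records)

    @given(
        counts=st.lists(st.integers(0, 500), min_size=2, max_size=20),
        split=st.integers(1, 19),
    )
    def test_pooling_is_area_weighted_mean_of_partition(self, counts, split):
        split = min(split, len(counts) - 1)
        records = _records(counts)
        left, right = records[:split], records[split:]
        pooled = density_per_m2(records)
        a_left = sum(r.area_m2 for r in left)
        a_right = sum(r.area_m2 for r in right)
        weighted = (
            density_per_m2(left) * a_left + density_per_m2(right) * a_right
        ) / (a_left + a_right)
        assert pooled == pytest.approx(weighted, rel=1e-12)


class TestEnergyDensityOp:
    def test_published_2021_sitka_value(self):
        assert round(energy_density(4.02, 4.684), 2) == 18.83

    def test_zero_density_gives_zero(self):
        assert energy_density(0.0, 123.0) == 0.0

    @given(
        d=st.floats(0, 1e3, allow_nan=False),
        e=st.floats(0, 1e3, allow_nan=False),
    )
    def test_commutative_and_bilinear(self, d, e):
        assert energy_density(d, e) == energy_density(e, d)
        assert energy_density(2 * d, e) == pytest.approx(2 * energy_density(d, e))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            energy_density(-1.0, 1.0)


class TestDensityTable:
    def test_consumed_never_exceeds_available(self):
        with pytest.raises(Exception):
            EnergyDensity(
                species=Species.SITKA_SPRUCE,
                year=2021,
                cones_per_m2_available=1.0,
                cones_per_m2_consumed=2.0,
                energy_per_m2_available_kJ=1.0,
                energy_per_m2_consumed_kJ=0.5,
            )

    def test_table_from_fixture_transects(self, fixture):
        table = cone_energy.energy_density_table(
            fixture.transects,
            {Species.SITKA_SPRUCE: 4.68, Species.LODGEPOLE_PINE: 5.292},
        )
        by_species = {d.species: d for d in table}
        ss = by_species[Species.SITKA_SPRUCE]
        assert ss.cones_per_m2_available == pytest.approx(5599 / 1650)
        assert ss.energy_per_m2_available_kJ == pytest.approx(4.68 * 5599 / 1650)

    def test_csv_round_trip(self, fixture, tmp_path):
        path = tmp_path / "energy_density.csv"
        cone_energy.write_energy_densities(fixture.densities, path)
        assert cone_energy.read_energy_densities(path) == fixture.densities
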