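# Methods

This note records the model the package implements, the parameter choices
that matter, what the synthetic data do and do not emulate, and the
numerical conventions, so results can be interpreted and the design
revisited with full context.

## The energy-budget model

The central quantity is the energy a forest's cone crop offers a red
squirrel population in one year. The chain is:

    seeds/cone  →  kJ/cone  →  kJ/m²  →  kJ (forest)  →  squirrels

Assumptions worth stating explicitly:

- **One seed per scale** on Sitka spruce cones. The seeds-per-scale
  factor is exposed in `SpeciesParams.seeds_per_scale` (default 1.0) for
  anyone wanting to discount for unfilled scales.
- **A one-year horizon** (`horizon_days = 365`): the autumn standing crop
  is treated as the year's food supply. This is the convention under
  which the packaged survey encoding reproduces every published capacity
  figure; shorter horizons (e.g. an overwinter period) can be configured
  and scale all head counts proportionally.
- **No alternative foods, no caching losses, no interspecific
  competition**: the estimate is a food-supply ceiling, not a demographic
  prediction.
- **Consumed energy identifies the standing population** via the same
  daily-requirement bracket. This assumes stripped cones found on
  transects represent the year's consumption in surveyed stands.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `daily_requirement_low_kJ` | 400 | kJ/day | low end of a red squirrel's daily energy need |
| `daily_requirement_high_kJ` | 700 | kJ/day | high end; the *low* capacity bound uses the *high* requirement |
| `horizon_days` | 365 | days | period one cone crop must feed the population |
| `area_density_per_ha` | 0.32 | squirrels/ha | literature density in a comparable spruce/pine forest, for the area-only estimate |
| `maturity_age_years` | 25 | years | stand age from which a usable cone crop is produced (inclusive) |
| `seed_energy_kJ` | 0.04 (spruce), 0.098 (pine) | kJ/seed | energy content of one seed |

**Lodgepole pine allometry.** Seeds per cone are predicted from mean
cone length. The default calibration is linear through the origin,
`seeds = length_mm × (54 / 42.8)` (≈1.262 seeds/mm), anchored so that
the mean 42.8 mm cone carries 54 seeds — the one anchor point available
from the Derryclare surveys; published pine-specific equations with more
coefficients can be injected through `SpeciesParams.allometric`
(`family: linear`, `slope`, `intercept`). Predictions far from ~40–50 mm
extrapolate a one-point calibration and should be treated cautiously.

**Rounding.** Squirrel counts and display hectares/percentages round
half away from zero (138.24 → 138, 81.53 → 82), the convention of the
published tables. Densities and energies are carried unrounded through
the pipeline; the conventional 2-decimal display applies only when
tables are rendered.

## The packaged Derryclare encoding

`derryclare_fixture()` is deterministic. It carries:

- the per-year stand ledger (2005, 2008–2011, 2021), with the 2011
  snapshot in its **pre-fire** state — the state the 2011 feeding survey
  sampled — and the post-fire state (58 ha of pine burned) as a separate
  stand list, since an integer year keys one snapshot;
- the published pooled per-m² cone and energy densities for each survey
  year, and the per-species occupied areas used to extrapolate
  consumption;
- the 2021 raw totals (5599 spruce cones, 136 consumed; 1032 pine cones,
  63 consumed over 1650 m²) spread deterministically over 33 transects;
- synthetic cone-measurement tables built from symmetric offsets so that
  the sample means are *exactly* the published ones (110 spruce scale
  counts with mean 117; 351 spruce lengths with mean 48.1 mm; 179 pine
  lengths with mean 42.8 mm). Their dispersion and correlation structure
  is schematic, not a reconstruction of the unpublished raw data.

Two internal inconsistencies in the published tables are resolved by
recomputation rather than transcription:

- The pooled 2021 spruce availability is published as 4.02 cones/m²,
  while the published raw totals give 5599/1650 = 3.39; which exclusions
  produced 4.02 was not recorded. The pipeline computes densities from
  counts when given raw transects, and uses the published pooled table
  (the basis of every downstream published figure) when reproducing the
  historical results; both routes are exposed and tested.
- The published consumed-energy forest totals disagree at the last
  digits with their own densities × occupied areas (e.g. 2,314,762 vs
  3.13 kJ/m² × 74 ha × 10⁴ = 2,316,200 kJ). The pipeline always
  recomputes density × area; every derived squirrel count is unaffected.

Similarly, per-cone energies are carried unrounded (117 × 0.04 =
4.68 kJ; 54 × 0.098 = 5.292 kJ); the published 4.69/5.28 evidently came
from unrounded seed means that were not printed.

## Synthetic survey generator

`SurveyDesign` draws per-transect available counts with mean
density × strip area, negative binomial by default (dispersion
k = 1.5) because cone crops under masting are strongly clumped between
stands — Poisson is available for idealised checks — and thins each
count binomially to give consumed cones, so consumed ≤ available by
construction. Cone lengths are Gaussian (truncated to the plausible
5–200 mm range); spruce scale counts are `slope × length + intercept +
noise`, rounded and floored at zero.

Default design values mirror the 2021 survey: densities 4.02 and 0.63
cones/m², consumed fractions 0.02 and 0.063 (the published consumed ÷
available density ratios), lengths 48.1 ± 8.2 mm and 42.8 ± 7.1 mm (SDs
back-computed from the published standard errors at n = 351 and 179),
scales slope 2.4/mm with intercept 1.56 (so the mean-length cone carries
117 scales) and noise SD 13 (which puts the length–scales R² near 0.7).

Seeding: one root seed; stream 0 → transect counts (transect-major,
species in declaration order, available before consumed), stream 1 →
cone measurements. Identical designs give identical tables.

What passing synthetic tests shows — and does not. The generator
reproduces marginal count dispersion, binomial consumption and the
linear scales–length law, so it validates estimator correctness,
determinism and calibration (e.g. rank-sum type-I error ≈ 0.05;
density/slope recovery within sampling error). It does not emulate
spatial autocorrelation between neighbouring transects, masting
time-series structure, observer error in cone species ID, or partial
cone consumption, so passing tests do not certify field performance
under those effects.

## Statistical choices

- **Density pooling** is total counts over total area (the area-weighted
  mean of per-transect densities), not the unweighted mean of
  per-transect densities; the two differ when strips differ in area.
- **Rank-sum test**: two-sided Mann–Whitney on per-transect densities.
  Exact null distribution when n₁·n₂ ≤ 400 with no ties; otherwise
  normal approximation with tie and continuity corrections. U is
  reported as min(U₁, U₂). Two-sided p-values are used throughout. No
  multiple-testing correction is applied (a handful of planned
  contrasts; raw p-values are reported).
- **Decline range** between two capacity intervals takes all four
  cross-pairings of before/after bounds and reports the min and max of
  100·(1 − a/b). Pairing like bounds with like would understate the
  uncertainty the two requirement brackets encode.
- **Composition correction** is only defined when all four cone
  densities are positive — a stand with no cones of one species cannot
  be corrected — and is intended for stands planted with pine as a nurse
  species for spruce, where self-thinning makes mapped composition go
  stale. Area reallocation computes the pine share as area − spruce
  share, so the parts sum to the input area exactly in floating point.
- **Maturity threshold** is inclusive (age ≥ 25) with integer ages
  (survey year − planting year).
- The 53% figure is the *reduction* of mature habitat from 2005 to 2021
  (432 → 202 ha, i.e. 230/432); the complementary 47% is the fraction
  *remaining*. The change report labels reductions explicitly to avoid
  conflating the two.

## Known limitations

- The energy budget ignores cone quality variation within species, seed
  predation by other taxa, and cached-versus-eaten partitioning.
- The one-point pine allometry and the one-year horizon are conventions,
  not estimates; both are configurable and all capacity numbers scale
  simply with them.
- The area-based estimate transfers a density from a different forest
  and carries no information about food supply; the package reports it
  alongside, not blended with, the energy-based interval.
- Occupied-area extrapolation treats occupancy as binary per stand;
  partial or seasonal occupancy is not modelled.
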