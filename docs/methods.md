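# Methods

## Incidence data model

The analysis unit is the sample unit (a 100 m square grid cell); a
species is counted at most once per unit regardless of how many stations
or rake tosses detected it. Units with zero detections stay in the
matrix and in `m` — they are genuine effort and the estimators depend on
them. Station-level long records, unit-level long records and wide 0/1
tables are all accepted; duplicate (unit, species) rows collapse
silently, unknown species or unit codes are hard errors naming the code.

Rarity is frequency-based: a species is rare at fraction `f` iff its
incidence frequency is strictly below `f` times the survey's total
incidences (strict inequality, matching the "< 5%" convention). The
Rare-20 endpoint applies the same rule at `f = 0.20`; the 20% reading is
a declared interpretation — the published tables name the column without
defining it, and the parallel column naming makes the percentage reading
the natural one. The native/non-native relationship is a per-unit
product-moment correlation; when either series is constant the
correlation is reported as NaN (undefined), never coerced to 0.

## Richness estimation

Chao2 with the finite-sample factor `A = (m−1)/m`:

* classic: `S_est = S_obs + A·Q1²/(2·Q2)`
* bias-corrected: `S_est = S_obs + A·Q1(Q1−1)/(2(Q2+1))`

The factor is not optional: without it the published survey values are
not reproduced (e.g. a 59-unit survey with S_obs 28, Q1 6, Q2 4 gives
32.4 with the factor and 32.5 without). Variances are variant-matched
(Chao 1987 / EstimateS appendix forms, including the no-duplicates form
when `Q2 = 0`), and the 95% interval is the log-transform interval: with
`T = S_est − S_obs` and `K = exp(1.96·sqrt(ln(1 + var/T²)))`, the bounds
are `(S_obs + T/K, S_obs + T·K)`, degenerating to a point when `T = 0`.
These choices reproduce published interval bounds to one decimal on every
row checked. Requesting classic with `Q2 = 0` falls back to
bias-corrected with a logged warning.

Variant selection follows the heterogeneity rule: classic iff the ICE
(Lee & Chao 1994) coefficient of variation exceeds 0.5. The gamma
formula is computed over infrequent species (frequency ≤ 10):
`γ² = max(S_inf/C_ice · m_inf/(m_inf−1) · Σk(k−1)Q_k / n_inf² − 1, 0)`
with coverage `C_ice = 1 − Q1/n_inf`. `m_inf` (units holding at least
one infrequent species) requires the matrix; when only summary counts are
available it defaults to `m`, which biases the CV slightly downward for
surveys dominated by frequent species — the full-matrix path in
`survey_report` uses the exact value. Zero coverage (all infrequent
species unique) yields CV = +inf and hence the classic variant.

## Rarefaction

Expected richness in `t` of `m` units is the analytic hypergeometric
form `E[S_t] = Σ_j (1 − C(m−s_j, t)/C(m, t))`, evaluated in log-gamma
space for numerical stability. The reported variance is the
unconditional estimator
`σ²(t) = Σ_j (1−α_jt)² − (Σ_j (1−α_jt))²/S̃` with `S̃` the classic Chao2
estimate, so the interval stays open at `t = m` (the survey, not the
assemblage, is the conditioning unit). A seeded resampling mode draws
unit subsets directly; it agrees with the analytic mean within
Monte-Carlo error and is used only for curve smoothing checks and the
"lowest possible accumulation" diagnostic (minimum over random unit
reorderings of the percent of `S_est` reached by the first few units — a
declared reading of a loosely defined published diagnostic).

## Effort projection

Additional units to reach a detection fraction `g` of the estimated
pool (incidence form of the Chao, Colwell, Lin & Gotelli 2009
extrapolation):

`m_g = ((m−1)·Q1/(2·Q2)) · ln( Q0 / ((1−g)·S_est) )`

computed always from classic-variant `S_est` and `Q0` — even for surveys
whose reported estimate is bias-corrected — because the published effort
columns are only reproduced with classic inputs. The prefactor carries
the same `(m−1)` finite-sample factor as the classic estimator;
with the bare `m` prefactor one published value falls outside its ±2
reproduction band, with `(m−1)` all six checked values fall inside and
two are exact. Results are rounded half-to-even; the value is 0 whenever
`S_obs/S_est ≥ g`, and `Q2 = 0` (with `Q1 > 0`) is an error directing the
user to bias-corrected extrapolation (not implemented here).

The full-census projection replaces the target gap with the point where
the expected number of uniques drops below one:
`m_100 = ((m−1)·Q1/(2·Q2)) · ln(m·Q1²/(2·Q2²))`. No candidate formula
reproduces the published S100% columns exactly (residuals of +30–60%
remain on the combined-survey rows); the implementation documents this
and asserts order of magnitude only.

## Similarity

Simplified Morisita (Morisita–Horn) on union-aligned incidence-frequency
vectors:
`C_H = 2Σx_iy_i / ((Σx_i²/X² + Σy_i²/Y²)·X·Y)`.
Symmetric, relabelling-invariant, 0 iff no shared species, 1 for
proportionally identical assemblages.

## Survey design

GRTS selection follows the published algorithm (Stevens & Olsen 2004)
rather than any proprietary GIS implementation: cells are scaled into a
2^L lattice, each quadtree node's four quadrants are independently
randomly permuted, cells are ordered by the resulting base-4 address
(ties broken by a seeded random key), and a systematic
probability-proportional-to-size draw with a random start is taken along
that order. Inclusion probabilities are therefore exactly
`π_i = n·w_i/Σw` (weights re-spread if any `π_i` would exceed 1). The
selected units are returned in reverse hierarchical order (ranks sorted
by reversed base-4 digits) so that any prefix is itself spatially
balanced — the field crew can stop early without losing balance. Spatial
balance is measured by the variance of Voronoi-neighbourhood inclusion
sums; GRTS beats simple random sampling on this metric in paired-seed
sign tests.

Weighting modes: uniform / zone-allocation (expected effort proportional
to the allocation, e.g. 75% shallow / 25% deep), depth strata, and
percentile-surface. Percentile ranks are computed over unmasked cells
only, using `(rank−1)/n·100` so exactly the top decile lands in the
≥90th class; the weight map defaults to 0.6/0.5/0.4/0.3/0.2 with floor
0.1. Masked (deep) cells keep the floor weight by default or can be
excluded. The per-zone minimum is `ceil(fraction × zone cell count)` by
default (the published design set 10% of each zone's total units as the
selection floor, surveying a subset), with a selection-size basis
available; deficits are filled from the zone's own reverse-hierarchical
order so additions stay balanced within the zone.

Richness surfaces are interpolated by inverse-distance weighting (power
2, exact at observations) by default; ordinary kriging with a
least-squares exponential-variogram fit is optional. The published
workflow used GIS kriging with unspecified parameters, and the
percentile map coarsens the surface anyway, so a reproducible monotone
interpolator is the sensible default. The depth mask (default 6 m,
using mean cell depth) can be disabled for sites that are not depth
limited.

## Habitat forest

`RandomForestRegressor` (500 trees by default, library-default split
rules, seeded) on the 18 habitat variables; the published analysis names
no hyperparameters and its numeric R²/importance tables are not
reproduction targets, only the reporting structure and selection rules
are. The train/test protocol is an 80/20 seeded split reported as
Training / Test / Overall rows, with Overall computed on all units
pooled. Importance is the sum over all trees of each variable's
impurity decrease (Gini sum), reported with its percent of the grand
total; the reduced model keeps variables at ≥5% of total importance and
drops the two soft-shoreline variables (impractical to derive
consistently for new sites). Predictions over a frame are clamped at
zero and feed the percentile weighting.

## Synthetic landscape and observation process

The generator emulates a coastal embayment: shoreline along one grid
edge, depth = 0.006 × shore distance + N(0, 0.4 m), clipped to
[0, 12 m] — so roughly half of a 2 km-deep frame exceeds 6 m, matching
the dispersed-design zero-detection regime. Shoreline thirds get
soft/hard/moderate types; boat launches, marinas and dock clusters sit
at seeded shore positions; all 18 habitat variables are derived from
these with distances measured from the cell edge.

Community: `S_true = 40` species, 20% non-native by count (after the
published one-fifth share), growth forms drawn with a 54% submerged
share. Occupancy per cell and species is
`base_j · logistic(depth; midpoint 4 m, scale 1 m) · suitability_cell ·
feature boost`, hard-zeroed beyond 8 m (no species occurs deeper in the
source surveys; most occur above 6 m). `base_j` is lognormal (σ = 1)
around 0.18 so that 40–80-unit surveys produce uniques and duplicates;
`suitability_cell` is a lognormal (σ = 0.5) multiplier shared by all
species, which induces the positive native/non-native richness
correlation; cells within 300 m of a launch or marina get a 1.5×
boost. Defaults give a dispersed-design zero-detection fraction of
~0.35–0.5, consistent with reported first-year surveys.

Observation: four stations per unit (fixed corner offsets), minimum four
rake tosses per station with per-toss per-species detection probability
0.25, continuing while the latest toss added a species new to the
station (capped at 12 tosses), plus a one-off 0.5 visual-detection
chance per station for floating, free-floating and emergent forms. The
visual meander is folded into this per-growth-form bonus rather than
modelled as a separate spatial process, and the field practice of
nudging units toward visible plant beds is representable as a detection
multiplier, not cell relocation — keeping the design strictly
probabilistic. No quantitative visual-detection rates exist to calibrate
against; the bonus values are free parameters and documented as such.

What the simulator does **not** emulate: light attenuation and real
bathymetry, species dispersal and interannual turnover, taxonomic
misidentification, and GIS-derived habitat layers. Passing tests
therefore demonstrate the internal consistency and statistical behaviour
of the estimators and designs under the stated generating model, not
field performance at any real site.

## Experiment harnesses and problem sizes

`recovery_experiment` scores Chao2 against the known true pool over
repeated seeded surveys; with the defaults (600-cell landscape, m = 20
vs 80, 200 seeds) the median absolute bias shrinks with effort.
`adaptive_vs_dispersed` pairs a single-stage uniform design of 40 units
against a two-stage design (20 uniform + IDW surface from stage-1
richness + 20 percentile-weighted from the remaining cells); the
adaptive design detects at least as many species in well over 60% of
paired seeds. These sizes keep the full suite to a few minutes while
leaving the Monte-Carlo tests well-powered; they are the package's
standard desk-scale configuration.

## Numerical choices and degenerate inputs

* Rounding: effort projections and detected-percentage use round-half-
  to-even; richness estimates are reported to one decimal.
* `Q1 = 0` collapses everything cleanly: `S_est = S_obs`, zero variance,
  point interval, zero projected effort.
* Binomial coefficients in rarefaction are computed via log-gamma;
  enumeration agreement is exact to 1e-12 on small fixtures.
* GRTS lattice depth is `ceil(log2(sqrt(n))) + 1` levels; co-located
  cells are separated by a seeded random tie-break key.
* IDW at an observed cell returns the observation exactly (zero-distance
  guard); constant observations short-circuit to a constant surface with
  no variogram fit.

## Known limitations

* The S100% census projection is indicative only (see above).
* The ICE CV from summary counts (without a matrix) approximates
  `m_inf` by `m`.
* Bias-corrected extrapolation for `Q2 = 0` surveys is not implemented;
  such surveys get NaN effort columns in reports.
* Ordinary kriging uses a single exponential variogram with no model
  selection or nugget diagnostics.
* The CLI handles planar coordinates only; no projection handling or
  shoreline digitization.
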