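# aquasurvey

Adaptive survey design and incidence-based richness estimation for early
detection of rare and invasive aquatic plants in large coastal areas.

Early-detection surveys for invasive aquatic plants face a hard question:
how much rake-and-boat effort does it take to be confident that the rarest
species in a 400+ hectare harbour or river mouth have been found?
`aquasurvey` implements a quantitative, probabilistic answer built around
replicated incidence data — presence/absence of each species across 100 m
grid-cell sample units — and an adaptive loop in which each year's survey
informs the next year's design.

It is aimed at monitoring programme analysts and quantitative ecologists
who need to (a) select survey locations probabilistically, (b) grade a
finished survey's completeness, and (c) decide where to put next year's
effort.

## What it computes

**Richness estimation.** With `m` sample units, observed richness
`S_obs`, `Q1` uniques (species found in exactly one unit) and `Q2`
duplicates (exactly two), the Chao2 estimator of total richness is, with
`A = (m-1)/m`:

- classic: `S_est = S_obs + A·Q1²/(2·Q2)`
- bias-corrected: `S_est = S_obs + A·Q1(Q1−1)/(2(Q2+1))`

each with a variant-matched variance and a 95% log-transform confidence
interval. The bias-corrected form is reported unless the incidence
distribution is strongly heterogeneous (ICE coefficient of variation
> 0.5), in which case the classic form is used.

**Effort projection.** The additional sample units needed to detect a
fraction `g` of the estimated pool:
`m_g = ((m−1)·Q1/(2·Q2)) · ln( Q0 / ((1−g)·S_est) )` with
`Q0 = S_est − S_obs`, using classic-variant inputs; plus a full-census
(`g = 1`) projection and sample-based rarefaction curves (analytic
hypergeometric expectation with unconditional variance, or seeded
resampling).

**Survey design.** Generalized random tessellation stratified (GRTS)
sampling: quadrant-recursive randomized addressing, systematic
probability-proportional-to-size selection, reverse hierarchical output.
Inclusion weights come from zone allocations (e.g. 75% of effort to the
shallow stratum), or from a predicted-richness surface mapped through
percentile classes (≥90th percentile → weight 0.6, ≥80th → 0.5, … <50th →
0.1), with a per-zone minimum quota and an optional 6 m depth mask.

**Habitat modelling.** A random-forest regression of per-unit richness on
18 habitat variables (depth, fetch, littoral extent, shoreline
composition, distances to boat launches / marinas / docks), with summed
Gini importances, the ≥5%-of-total-importance reduced-model rule, and a
depth-only baseline; predictions feed back into the percentile weighting.

**Similarity & endpoints.** Simplified Morisita (Morisita–Horn) overlap
between designs, per-unit means of total / rare / non-native richness,
and the native-vs-non-native richness correlation.

A synthetic-landscape module generates coastal grids (depth increasing
offshore, no plants beyond 8 m), heavy-tailed plant communities with a
shared richness driver, and the four-station / four-plus-rake-toss
observation process with its "stop when nothing new" rule, so the whole
pipeline can be exercised and validated at desk scale.

## Worked example

Evaluate a finished survey from its summary counts (78 units, 43 species,
4 uniques, 3 duplicates):

```python
from aquasurvey import IncidenceCounts, survey_report

rep = survey_report(IncidenceCounts.from_q(78, 43, 4, 3), site="detroit")
print(f"Sest = {rep.sest:.1f}  (95% CI {rep.ci_low:.1f}-{rep.ci_high:.1f})")
print(f"S95% = {rep.s95_additional:.0f} additional units; "
      f"detected {rep.percent_detected}% of pool")
```

prints

```
Sest = 44.5  (95% CI 43.2-55.3)
S95% = 7 additional units; detected 97% of pool
```

i.e. an estimated pool of 44.5 species of which 97% has been detected,
with roughly 7 more sample units projected to reach 95% detection.
Simulate a survey end-to-end and redesign from its observations:

```python
from aquasurvey import (LandscapeConfig, CommunityConfig, ObservationConfig,
    generate_landscape, generate_community, spatially_balanced_sample,
    simulate_survey, survey_matrix, survey_report, interpolate_richness,
    assign_weights)

landscape = generate_landscape(LandscapeConfig(seed=1))       # 30 x 20 cells
community = generate_community(landscape, CommunityConfig(seed=2))
units = spatially_balanced_sample(landscape, 40, seed=3)
records = simulate_survey(community, units, ObservationConfig(seed=4))
matrix = survey_matrix(community, units, records, landscape)
rep = survey_report(matrix, site="synthetic")
print(f"sim Sest = {rep.sest:.1f} ({rep.variant}), detected {rep.percent_detected}%")

surface = interpolate_richness(matrix.per_unit_richness().to_dict(), landscape)
next_frame = assign_weights(landscape, "percentile_surface", surface=surface)
```

prints `sim Sest = 37.8 (classic), detected 87%` against a true pool of 40
species, and `next_frame` carries the percentile weights for the next
year's GRTS draw. The same loop is available from the shell via the
`aquasurvey` CLI (`design`, `simulate`, `evaluate`, `compare`, `report`).

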