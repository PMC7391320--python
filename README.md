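# reefcascade

Trend detection and community-level trophic-cascade classification for
long-term reef monitoring data.

Reef monitoring programs count predators and herbivores on transects and
measure algal cover, year after year, at sites nested within locations that
span tropical coral reefs to temperate rocky reefs. `reefcascade` answers,
for each location: are any of the three trophic groups (predators,
herbivores, algae) changing significantly over time; do adjacent groups move
in concert (bottom-up, resource-driven forcing) or in opposition (top-down,
consumer-driven forcing); and do all three groups show *alternating*
significant trends — predators up, herbivores down, algae up, or the mirror
pattern — the signature of a community-level trophic cascade? Across
locations it then models how these diagnostics vary with latitude and
exploitation status (no-take marine reserves vs fished areas).

It is written for community ecologists working with hierarchical survey
tables (transect → site → location) and for anyone who wants a tested,
reusable implementation of this style of time-series food-web analysis,
including a synthetic data generator for power and calibration studies.

## The statistics

For each location and trophic group, the annual series of mean density
(mean over transects within a site-year, then over sites within a year) is
standardized to mean 0, sample standard deviation 1, making trends
comparable across survey programs with different units. Trends are tested
by OLS of standardized site-year values on year (t test on the slope,
two-sided, α = 0.05), with a generalized least squares variant in which
sites within a year share a latent year effect whose correlation decays as
ρ^|Δt| (AR-1), estimated by REML — more conservative when consecutive years
are dependent, applicable where site sampling is even across years.

Forcing is diagnosed from the Pearson correlation r between adjacent
groups' annual series: r < 0 suggests top-down, r > 0 bottom-up control.
For cross-location comparison each r is carried as Fisher's
z = atanh(r) ~ Normal(·, 1/(n−3)), and z is regressed on latitude by
weighted least squares with weights n − 3 (meta-analytic inverse-variance
weighting); fits and confidence bands are mapped back through tanh.
A location is classified *alternating* when all three trends are
significant with opposite adjacent signs, conditional on a significant
predator trend (the top-down prerequisite). The occurrence of alternating
trends among predator-significant locations is modelled by a binomial GLM
(logit link) in latitude and exploitation status, simplified by backward
stepwise removal of nonsignificant terms (p > .05) guided by AIC.

## Worked example

Simulate a study-structured dataset (104 locations, tropical to temperate,
four exploitation categories, a mix of cascade, bottom-up and null forcing
regimes) and run the full chain:

```sh
reefcascade run --out-dir demo --seed 2 --method ols
```

prints (machine-readable `summary.txt`; full detail in `demo/report.txt`):

```
wls_predator_herbivore_latitude_coef=0.010763
wls_predator_herbivore_latitude_p=0.299248
wls_predator_herbivore_r2=0.01056
wls_herbivore_algae_latitude_coef=0.014321
wls_herbivore_algae_latitude_p=0.197868
wls_herbivore_algae_r2=0.016202
n_locations=104
n_predator_significant=25
n_predator_increasing=17
n_predator_decreasing=8
n_alternating=4
pct_alternating=16.0
excess_over_chance=4.8077
glm_retained_terms=latitude
n_excluded=0
n_true_cascade_regime=4
n_cascade_recovered=4
```

Reading: 25 of 104 locations show a significant predator trend (17
increasing, 8 decreasing) — about 4.8 times the 5.2 expected by chance at
α = .05. Four locations (16% of the predator-significant ones) show the
full alternating pattern; all four are the generator's true top-down
cascade regimes (`n_cascade_recovered`). Stepwise selection retains
latitude, not exploitation status, in the cascade-occurrence GLM. The
weighted Fisher-z regressions report the latitudinal gradient in
adjacent-group correlations (positive coefficients: correlations become
more positive toward the equator, since southern latitudes are negative).

Intermediate tables (`surveys.csv`, `series.csv`, `trends.csv`,
`correlations.csv`, `cascade.csv`, `prevalence.csv`, `truth.csv`) are
written alongside; the same stages are available individually as
`reefcascade simulate | aggregate | trends | classify | infer`, or from
Python via `reefcascade.run_pipeline` and the underlying library functions.

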