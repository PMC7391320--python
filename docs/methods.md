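# Methods

This note documents the statistical model behind `reefcascade`, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Data model and aggregation

Input is a long-format survey table: one row per transect-level trophic
group total at a site in a year, for three groups — predators, herbivores
(densities, individuals per transect) and algae (percent cover). Cover is
planar (≤ 100%) at tropical locations and three-dimensional
(benthos-to-canopy, may exceed 100%) at temperate ones; temperate cover is
deliberately not capped, since all comparisons are within a location.

The hierarchy is collapsed in two unweighted steps: transect values are
averaged within each site-year, and site-year means are averaged across the
sites present that year. The site is the replication unit (transects are
contiguous and not independent at temperate sites). Missing years are
simply absent; no imputation. Trend analysis at a reserve starts at the
reserve-implementation year; fished locations matched to the same
geographic area use that reserve's start year (supplied in the metadata) to
control for shared temporal factors.

Each location × group annual series is standardized to mean 0, sample
(n−1) standard deviation 1. The constants are computed from the
location-level annual means and re-applied to the site-year means, so the
regression's replicate points live on the series' scale. This choice (one
of two defensible conventions) is covered by an invariance property:
Pearson correlations and trend p-values are unchanged by any positive
affine rescaling, so downstream statistics do not depend on it.

Quality control: a series must span ≥ 3 distinct years and ≥ 12 surveys
(unique year × site combinations) and must not be constant. The validator
reports failures; the pipeline excludes flagged locations and logs a
reason code rather than failing silently.

## Trend tests

**OLS.** Standardized site-year values are regressed on centred year; the
slope is tested with t = b/se on n_points − 2 degrees of freedom,
two-sided, α = 0.05 by default, with no multiple-testing correction (each
location is reported at raw α; the analysis explicitly compares the count
of significant results to the chance expectation n·α instead). A zero
residual-variance fit is reported as significant with p = 0 and an
exact-fit flag; it cannot occur under the continuous generator.

**AR-1 GLS.** Residual model y = a + b·t + u_year + e with stationary AR-1
year effects, Cov(u_t, u_s) = σ_y²·ρ^|t−s|, shared by all sites within a
year, plus white noise. ρ (profiled on [0, 0.95]) and the variance ratio
are estimated by REML; plain ML after detrending biases ρ down strongly at
these series lengths (Monte Carlo at T = 19, true ρ = 0.6: ML ≈ 0.32, REML
≈ 0.53), and REML matches standard GLS practice. The slope test uses
n_years − 2 degrees of freedom, treating the year as the effective
replication unit, which is what makes the variant conservative. The model
applies only where the same site set was surveyed every year; elsewhere the
fit reports not-applicable and the OLS result stands. When the fitted
year-effect variance is negligible (ratio < 1e-4), ρ is unidentified and
reported as 0.

## Forcing diagnosis and cascade classification

The Pearson correlation between two adjacent groups' annual series (over
their common years, ≥ 3 required) diagnoses forcing: negative = top-down,
positive = bottom-up. Correlations are computed between series
trajectories, not between fitted slopes. For cross-location models each r
becomes Fisher's z = atanh(r) with variance 1/(n−3); weights are n − 3,
floored at 0, so 3-year series are excluded from weighted fits (and the
exclusion counted). |r| = 1 has an infinite transform and is excluded with
a flag.

A location is *alternating* iff all three trends are significant and
adjacent signs are opposite — patterns P+H−A+ or P−H+A−, both admissible by
symmetry — conditional on the predator trend being significant (the
prerequisite: without a change at the top there is nothing to cascade).
Opposing significant predator–herbivore trends without a significant algae
trend are tallied separately as `partial_alternating`. Prevalence is
reported as alternating / predator-significant, with the exact fraction
retained and an integer-rounded display value. Under the null, the
alternating rate has a theoretical ceiling of roughly 2·(α/2)·α² ≈ 3×10⁻⁵
per location (three independent tests at α times the 2-of-8 admissible sign
patterns), verified by Monte Carlo at 10,000 null locations.

## Cross-location models

Fisher-z values are regressed on signed latitude (degrees, negative =
south, so the equator sits at 0 and "more temperate" is more negative) by
weighted least squares; fits and 95% normal-approximation bands are mapped
through tanh for presentation, which also guarantees bands within [−1, 1].
Per-group trend slopes are regressed on latitude and, separately, on
exploitation status, weighted by the inverse squared slope standard error,
and per-category weighted mean slopes with 95% CIs are emitted.

Alternating-trend occurrence among predator-significant locations is
modelled by a binomial GLM with logit link, latitude (continuous) plus
exploitation status (treatment contrasts, `always_fished` reference).
Categories with fewer than 5 locations trigger a warning; separation is
detected (|coefficient| > 12 on the log-odds scale, or fitted probabilities
all at the boundary) and flagged, not corrected.

**Backward stepwise selection.** From the full model, among terms with
p > .05, drop the one whose removal lowers AIC the most; refit; stop when
all remaining terms are significant or no removal lowers AIC (an
intercept-only endpoint is valid). Multi-level categorical terms are tested
as a block — likelihood-ratio χ² for the GLM, F test for least squares —
because per-level Wald p-values cannot justify dropping a whole factor.
Note the rule's two conditions can disagree: a 2-df block with LR between 4
and 5.99 is nonsignificant yet its removal raises AIC; the term is then
kept, per the AIC guard.

## Synthetic data generator

Each location carries three latent log-density series
m_g(t) = α_g + β_g·t̃ + u_{g,t} over centred years t̃, with a stationary
AR-1 year effect u (marginal sd σ_year, autocorrelation ρ) shared by all
sites in a year, a time-constant site effect (sd σ_site), and lognormal
transect noise (sd σ_obs): value = exp(m + a_s + e). The log-linear form
guarantees non-negative densities; per-series standardization makes the
latent scale immaterial downstream. Algae are emitted as percent cover via
fixed baseline scales (≈ 8% tropical, ≈ 40% temperate; planar tropical
cover capped at 100, which essentially never binds at the default noise
levels). Slope vectors encode the regime: top-down cascade (b, −λb, +λ²b)
with attenuation λ per trophic step (or the global sign flip; positive
predator slope by default, since every observed cascade sat on a rising
predator trend), bottom-up (λ²b, λb, b), null (0,0,0), or independent
N(0, slope_sd²). Herbivore and algae year-effect innovations can be
cross-correlated to impose a target adjacent-pair correlation. A master
seed spawns independent per-location substreams
(`numpy.random.SeedSequence`), so output is reproducible and location i's
draws do not depend on how many locations are generated.

**Default scenario** (104 locations): 60 tropical (3 sites each), 24 warm-
and 20 cool-temperate (3–14 sites), series of 5–19 years ending 2013,
5 transects, exploitation statuses in the study's proportions
(36/15/50/3). Twenty-four locations carry forced trends — per 104: 12
rising and 8 declining bottom-up, 4 top-down cascades (1 tropical, 3
temperate), with 9–19-year series — and the rest are null, mirroring the
observed composition of 24 predator-significant locations (16 up, 8 down)
with four alternating. Default variances σ_year = 0.05, σ_site = 0.3,
σ_obs = 0.3, ρ = 0.2: most noise is spatial, so the replicate-level OLS
test stays conservative at null locations and the forced composition is
recovered cleanly. The paper trail for these values is power analysis, not
field estimates — the source study publishes no variance components — so
they are package choices, stated here once.

**Calibration scenario** (`null_config`): all regimes null, with *only* iid
transect noise (σ_year = σ_site = 0, ρ = 0). This is the regime in which
the replicate-level OLS t test satisfies its assumptions, so its
false-positive rate equals α — the property the calibration suite checks.
With shared year effects the realized level deviates from α in either
direction depending on the site count (pseudo-replication); that deviation
is a property of the replicate-level test, is why the AR-1 variant exists,
and is deliberately not presented as a calibration defect.

**Gradient scenario** (`latitude_gradient_config`): herbivore–algae
innovation correlation running +0.4 (14°S) to −0.4 (43°S), bottom-up
trends in the tropics and weak top-down cascades (b = 0.04, σ_year = 0.15)
in temperate locations, so only ~half the temperate cascades are recovered
as alternating — enough signal for the latitude term, enough failure to
keep the logistic fit away from separation — with exploitation assigned
independently of everything (a truly null factor).

**What the generator does not emulate:** species-level composition and
turnover, observer and method effects between programs, mechanistic
consumer–resource (predator–prey) dynamics, environmental covariates, gaps
within series, and unbalanced site sets across years (it always samples
sites evenly, so the AR-1 variant applies everywhere). Passing recovery
tests therefore show the *statistical machinery* behaves as claimed under
the assumed noise structure, not that real reef data satisfy that
structure.

## Numerical and reporting conventions

Standardization requires sd > 0; constant series are flagged and their
trends reported non-significant. Direction is `none` iff p > α; otherwise
the slope's sign. Percentages are displayed at integer precision with
exact fractions retained in machine output; a prevalence denominator of
zero yields an undefined (not 0%) percentage. The AR-1 optimizer runs
L-BFGS-B from three starts; non-convergence is flagged and the OLS result
used. Problem sizes in the test and acceptance suites (1,000-location
calibration, 10,000-location alternating-rate ceiling, 100-location regime
recovery, 20 gradient replicates) were chosen to give 3-sigma Monte-Carlo
resolution on the quantities checked while keeping a full run in the low
minutes on one core.

## Known limitations

Replicate-level OLS understates year-to-year dependence when year effects
are large and sites many; use the AR-1 results in that regime. The Fisher-z
weighting treats annual series values as n independent draws, which
overstates information for autocorrelated series. Stepwise selection
inherits the usual post-selection inference caveats — reported p-values for
retained terms are conditional on the search. Separation in the cascade GLM
is flagged but not penalized (no Firth correction). Biomass-based analyses
are out of scope; all trends are density/cover trends.
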