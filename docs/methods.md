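# Methods

## The problem

Spring phenological events — budburst and flowering — are observed in two
very different ways: intensive long-term monitoring of a few sites on a
regular 3–7 day schedule, and broad-scale status monitoring in which many
observers record, on irregular visits, whether a phenophase is currently
present on an individual plant. This package implements the full chain
needed to ask whether phenology models fit to the two kinds of data agree:
event inference from status records, model fitting, and cross-collection
comparison statistics, exercised end to end on synthetic data with known
truth.

## Data model

All temperature-driven computation runs on a season-relative day-of-year
(DOY) grid from −90 to 250, where DOY 1 is 1 January of the event year and
negative DOY indexes the preceding autumn. The grid brackets temperate
spring events with margin on both sides: the start-day parameter t₁ may be
fitted as far back as DOY −30 (accumulation beginning in December), and no
admissible event falls after DOY 213. Missing days are explicit NaN gaps;
computations that need a window (e.g. the spring mean) raise on gaps rather
than interpolate.

The estimator design matrix has one row per observed event: the 341 daily
temperatures of the event's site-year followed by site latitude. Every
model covariate — spring mean temperature (DOY 1–90), the running chill-day
count, the photoperiod — is derived from that row, which keeps the
estimators compatible with scikit-learn's fit/predict conventions and model
selection tools.

## Models

Eight models are implemented (see README for the table): a constant
(mean-DOY) predictor, a linear regression on spring mean temperature, and
six forcing-accumulation models (GDD, Fixed GDD, Alternating, Uniforc, M1,
MSB). Conventions that the formulas alone do not fix:

- **Threshold crossing** uses ≥: the event is the first day the running
  total meets the requirement, including that day's contribution.
- **Day-varying requirements** (Alternating, MSB via the chill-day count;
  M1 via photoperiod) are re-evaluated every day with that day's covariate
  value.
- **Chill days** count days with mean temperature strictly below 0 °C,
  from 1 January onward.
- **Spring window** is DOY 1–90 in all years; 29 February, when present in
  source data, is an ordinary calendar day.
- **t₁ is an integer day**; continuous optimizer proposals are rounded to
  the nearest integer before prediction. Bounds default to [−30, 120]; use
  of negative start days is supported since the temperature grid reaches
  back to DOY −90.
- **Uniforc's sigmoid slope b is constrained negative** ([−20, −0.1]) so
  that forcing increases with temperature.
- **M1's forcing floor**: the daily forcing defaults to
  max(Tᵢ − T_base, 0), consistent with the GDD family and the model's
  original daylength-correction formulation; a `forcing_floor=5` switch
  selects the variant with a minimum daily forcing of 5 units.
- **No-event marker**: a parameter vector whose requirement is never met
  within the season window yields NaN, the package-wide no-event marker in
  prediction arrays. The fitting objective maps it to a fixed 1000-day
  residual — far beyond any real residual — which keeps the objective
  finite while pushing the optimizer away from degenerate regions.
- **Photoperiod** uses the Forsythe et al. (1995) CBM day-length model with
  the standard daylight definition (sun centre at the horizon). Latitudes
  beyond ±66° are refused; there are no polar sites in scope.

## Event inference from status records

A status record is one yes/no/unsure assessment of one phenophase on one
plant on one date. Cleaning proceeds per plant–phenophase–calendar-year:
"unsure" records are dropped; duplicates collapse with a same-date yes/no
tie resolving to yes (logged); the first "yes" of the year yields an event
only if a "no" precedes it by at most 30 days (15 in the sensitivity
setting), with the event DOY the midpoint of the pair, half-integers kept.
Budburst events after DOY 172 and flowering events after DOY 213 are
treated as outliers and dropped, and species–phenophase groups with fewer
than 30 events (counted after the cutoff filter, ≥ by default) are removed.
Individual plants are never pooled into a site-level series. Intensive
protocols that record numeric metrics (percent buds open, flowering counts)
are converted to yes/no with a configurable threshold, default "any
positive value is yes".

## Fitting

All models are fit by `scipy.optimize.differential_evolution` minimizing
the RMSE of predicted event DOY — a global, derivative-free method, needed
because the accumulation models predict integer days and the objective is
piecewise constant. Defaults: population ≈ 30 members (scipy's per-parameter
multiplier is converted accordingly), mutation dithered in [0.5, 1.0],
recombination 0.7, at most 500 generations, tolerance 10⁻³ days, Latin
hypercube initialization, seeded and bit-reproducible. Default bounds span
published fits while keeping the search compact: F\* ∈ [0, 1000]
(Uniforc [0, 200], since its daily forcing is ≤ 1), T_base ∈ [−10, 15] °C,
t₁ ∈ [−30, 120], a ∈ [0, 1000], b ∈ [0, 2000], c ∈ [−2, 0],
d ∈ [−200, 200], k ∈ [0, 50], β₁ ∈ [0, 250], β₂ ∈ [−20, 20].

Uncertainty comes from an n-out-of-n bootstrap (default 250 refits on
resamples drawn with replacement). The optimizer seed is fixed across
bootstrap repetitions so that all randomness lives in the resampling —
identical resamples give identical refits, and a degenerate dataset of
repeated observations yields exactly zero parameter spread. A failed refit
is retried once on a fresh resample, then recorded as missing and excluded.
Downstream predictions default to the mean of the per-bootstrap predicted
DOYs, with no-event draws excluded whenever at least one bootstrap predicts
a real date; point-parameter prediction is available everywhere as an
alternative. Evaluation holds out 20% of events per species–phenophase
group (banker's rounding, minimum one event, refused below five events).

## Comparison statistics

Two fitted collections (conventionally A = intensive, B = broad) are
compared three ways. Parameter agreement and prediction agreement use the
identity-line R², 1 − Σ(yᵢ−xᵢ)²/Σ(yᵢ−ȳ)²: deviation from the 1:1 line
relative to the variance of y, equal to 1 at perfect agreement and
unbounded below. The A value is x and the B value y, so the variance anchor
is the broad-scale collection; the opposite ordering can be computed by
swapping arguments. Out-of-sample error uses per-group holdout RMSE
differences (A minus B) on the same events, tested against zero with a
two-sided one-sample t-test; zero variance across groups is reported as
degenerate with the mean only. Pearson correlations are available
alongside. No multiple-testing correction is applied — p-values are raw,
by design, and flagged as such here.

## Synthetic data

The generator emulates the structure the analysis depends on, not any
particular landscape:

- **Climate**: Tᵢ(d) = M(lat) + A·cos(2π(d − peak)/365) + ε with
  ε ~ N(0, σ_daily), defaults M = 12 °C at 40° N with −0.7 °C per degree of
  latitude, A = 13 °C, peak DOY 200, σ_daily = 3 °C — a plausible
  mid-latitude seasonal cycle. White noise only: no day-to-day
  autocorrelation, no warming trend, a documented simplification (forcing
  sums average over weather, so autocorrelation mostly affects the variance
  of event dates, not their mean).
- **Truth**: a chosen forcing model (default Fixed GDD, F\* = 200) with a
  per-species parameter draw (default sd 40 across species), an optional
  per-site deviation (`param_spatial_sd`, the "local adaptation" scenario),
  and N(0, 2 d) individual noise applied to the realized date — not to the
  threshold — then rounded to the day.
- **Campaigns**: eight seasons (2009–2016) by default; 2 intensive sites
  with 5 individuals per species visited on a regular interval drawn from
  3–7 d, versus 20 broad-scale sites with 3 individuals visited on random
  days at rate 0.1/day with 30% of individual-years dropped entirely. Each
  visit records "no" before the true date and "yes" on or after it, so the
  cleaning pipeline faces genuine interval censoring.

Everything is reproducible from the single config seed; each site-year's
weather stream has its own derived seed so any series can be regenerated in
isolation. What passing tests on these data do **not** show: robustness to
observer error (false positives/negatives), spatially clustered sampling
bias, precipitation-driven phenology, or real climate structure.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run scaled-down versions of the
experiment: 200-event regimes for parameter recovery, four-season
campaigns, and 10 replicates of the scale-transfer contrast (20 broad vs 2
intensive sites, site-varying F\* with sd 40). These sizes give stable
outcomes (e.g. the recovery check lands within a fraction of a percent of
the generating F\*) while keeping a full run to minutes on one CPU.

## Known limitations

- The two-phase chilling models (e.g. Unichill) and precipitation drivers
  are out of scope.
- The binary converter for intensive metrics is a single generic threshold
  rule; real protocols may need dataset-specific conversions.
- Event inference pairs records within a calendar year; a "no" in late
  December cannot anchor a "yes" in early January.
- Identity-line R² with fewer than ~10 groups is a noisy summary; the
  pipeline reports it regardless because it is the analysis's headline
  statistic.
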