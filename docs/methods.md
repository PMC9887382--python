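# Methods

This note documents the models behind `namdcast`, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions a maintainer needs to know.

## Visual-acuity handling

VA is carried everywhere as approximate ETDRS letters (integers 0–100;
85 ≈ normal vision).  Snellen fractions are converted with
`letters = 85 + 50·log10(numerator/denominator)`, rounded half-up and
clamped to [0, 100].  This is the standard logMAR-based approximation and
reproduces the three clinical equivalences the analysis relies on
(6/12 ↔ 70, 6/96 ↔ 25, 3/60 ↔ 20).  The rounding convention is round-half-up
rather than banker's rounding; at the equivalences above the unrounded
values (69.95, 24.79, 19.95) are not at a half, so the choice only matters
for other fractions.

Ages arrive deidentified in six bands (<65, 65–69, …, 85+).  Where a
numeric covariate is needed (propensity and VA models) the band midpoint is
used: 60 for <65 and 88 for 85+, the interior bands at their midpoints.
These two open-ended values are pragmatic pseudo-midpoints for an elderly
nAMD population; sensitivity to them is low because age enters linearly
with a small coefficient in both models.

Summary statistics use the sample (n−1) standard deviation; a
single-observation group reports sd = 0 so summaries stay numeric.  The
two-centre VA comparison uses the Welch unequal-variance *t*-test computed
from summary statistics, so it can also be evaluated on published tables.

## Forecasting

The weekly initiation series is modelled additively: trend + seasonal +
random, with seasonal period m = 52 (one annual cycle of a weekly series;
the period is a parameter, not a constant).  Decomposition is the classical
one (centred moving average of window m; period-averaged detrended values
re-centred to sum zero) as implemented by
`statsmodels.tsa.seasonal.seasonal_decompose`.

Forecasting uses additive Holt-Winters exponential smoothing with the
textbook recursions.  Design choices the method itself does not fix:

* **Initialisation.**  Seasonal indices from the decomposition of the first
  two cycles; level and trend from a least-squares line through the first
  cycle's trend component, evaluated one step before the first observation.
  On a noiseless trend + seasonal series this initialisation is exact, which
  is what lets the test suite pin the implementation against the generating
  closed form at 1e-6.
* **Smoothing parameters.**  When not supplied, (α, β, γ) minimise the
  in-sample one-step sum of squared errors, by L-BFGS-B over [0,1]³ seeded
  from the best point of a 3×3×3 grid.
* **Prediction intervals.**  Gaussian, ± 1.96·σ̂·√h where σ̂ is the RMS
  one-step residual.  Points and lower bounds are truncated at zero because
  counts cannot be negative.
* **Totals.**  The window total is the rounded sum of unrounded weekly
  points, not a sum of rounded points, to avoid accumulating rounding bias.
* Each centre is fitted and forecast independently; the default run fits on
  every available pre-interruption week (2018-W01 through 2020-W11) and
  forecasts 2020-W12 through 2020-W31.

## Sampling

The hypothetical cohort for a centre is a uniform random sample, sized by
the forecast total, from that centre's patients whose index week lies in
ISO weeks 12–31 of 2018 or 2019 (both years pooled).  Sampling is without
replacement when the pool suffices, with replacement otherwise (logged).
Sampled patients get fresh ids carrying the draw index so repeated draws
remain distinguishable.

## Matching

Patients with baseline VA outside the trial eligibility window are excluded
before matching.  The default window is **[25, 70] letters inclusive** — the
treatment floor and the good-vision threshold.  The trial's actual inclusion
bounds are not published at letter precision; these two clinically anchored
values reproduce the qualitative non-matching pattern (most non-matched
patients sit above 70) and the window is a configuration value, not a
constant.

The propensity model is unpenalised maximum-likelihood logistic regression
(statsmodels `Logit`) of cohort-vs-sham membership on age-band midpoint,
sex (female = 1) and baseline VA.  Perfect separation raises an error
rather than returning degenerate scores.

Matching is greedy best-first 1:1 without replacement: all cross-group
pairs within the calliper — 0.1 × SD of the logit propensity, SD taken over
the pooled fitted subjects — are admitted in ascending |Δ logit|, ties
broken by (profile id, participant id) so the result is deterministic and
invariant to input order.  An exhaustive oracle in the test suite pins this
behaviour on small instances.  Greedy best-first is near-optimal for
calliper matching and is transparent to audit; optimal (assignment-problem)
matching is deliberately out of scope.  An exact-matching mode on
(age band, sex, VA) is available behind a flag for comparison but is not
the default, since a calliper on the propensity logit is the better-defined
procedure when covariates are mixed-scale.

## Projection

Matched patients inherit their sham partner's **change from baseline**:
va(t) = clamp(own baseline + (partner va(t) − partner baseline), 0, 100).
Carrying the change (rather than the partner's absolute VA) keeps the
projected cohort's baseline distribution equal to the sampled cohort's,
which is what the pooled baseline bars in the outcome summaries assume.
Partner visits missing a horizon month are linearly interpolated between
adjacent visits; trailing gaps carry the last observation forward.

Unmatched patients are projected with one OLS model per horizon month
(3, 6, 12) of observed sham VA on age-band midpoint, sex and baseline VA,
fitted on the sham arm only and requiring at least 10 participants per
month.  Per-month models make no linearity-in-time assumption; a single
model with month as a covariate would.  Predictions are clamped to
[0, 100]; a baseline outside the training VA range is logged as
extrapolation but still predicted.

The horizon grid is months {0, 3, 6, 12}.

## Outcomes

Trajectories are completed on the grid by last observation carried forward,
guaranteeing constant denominators, then summarised per centre and month:
mean ± sample SD of VA and counts/percentages for VA ≥ 70 (inclusive),
VA < 25 (strict) and VA ≤ 20 (inclusive), percentages to one decimal.
Matched and modelled subgroups are summarised separately and pooled with
exact recombination: counts add, means recombine size-weighted, and SDs
recombine through the pooled-variance formula including the between-group
mean shift, so pooling two subgroup summaries equals summarising the union.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, with
defaults fixed to the published study conditions:

| parameter | default | basis |
|---|---|---|
| MEH weekly level | 16.3 /week | ≈ 325 initiations over the 20-week window |
| UHB weekly level | 2.55 /week | ≈ 51 over the window |
| weekly trend | 0 /week² | no secular drift reported |
| seasonal amplitude | 2.0 (MEH), 0.6 (UHB) letters·sin cycle, period 52 | modest annual cycle, small relative to level |
| count noise | Poisson | count data |
| MEH margins | 60.5% female; age/ethnicity/smoking per published table; VA 55.9 ± 16.3 | published baseline table |
| UHB margins | 68.5% female; VA 51.7 ± 20.0 | published baseline table |
| profile VA truncation | [0, 95] | ETDRS range actually observed at baseline |
| sham n | 238 | trial sham-arm size |
| sham baseline VA | 53.61 ± 14.06, truncated-normal, integer | trial baseline column |
| sham mean 12-month change | −9.3 letters | published matched-cohort decline 52.9 → 43.6 |
| sham between-subject 12-month slope SD | 12 letters | realistic natural-history heterogeneity |
| sham visit months | 0, 3, 6, 12, 24 | horizon months plus trial follow-up |
| visit noise SD | 2 letters | ETDRS test–retest repeatability |

Per participant the sham VA is baseline + slope·month + noise, rounded and
clamped to [0, 100], with the month-0 visit pinned to baseline.

**What the generators do not emulate:** covariates are drawn independently
(no age–VA or sex–smoking correlation; a correlation knob exists in design
but margins are all the published tables provide); presentation behaviour
during the interruption itself (the whole point of the counterfactual);
fellow-eye conversion; concurrent ocular comorbidity, which in real data
would accelerate VA loss — so passing tests demonstrate the pipeline's
correctness and calibration against its own generating assumptions, not
the clinical accuracy of the published projections.

## Problem sizes and numerical conventions

The default scenario runs the full published scale (1929 + 267 profiles,
238 sham participants, 115-week histories) in seconds; the test suite uses
smaller cohorts (≤ 600 profiles, ≤ 300-patient end-to-end recovery runs at
20 seeds) chosen to keep Monte-Carlo error well inside the asserted
tolerances.  A single top-level seed derives per-stage seeds by stage-name
hashing, so every stage is independently reproducible and a rerun with the
same seed reproduces every output byte for byte.

Ties and degenerate inputs: simultaneous bilateral diagnosis designates the
right eye; matching ties break lexicographically; a zero calliper admits
only exact logit ties; zero matches is a valid, logged outcome; empty
cohorts and too-short series raise errors naming the offending input.

## Known limitations and recorded discrepancies

* The published pooled baseline share of eyes ≥ 70 letters at the larger
  centre is printed three ways at source (25% = 83/325 in the text, 25.5%
  in the abstract, and subgroup counts summing to 77/325).  The packaged
  fixtures carry all three variants without adjudicating.
* The source describes its matching both as a propensity calliper and as
  "matched exactly"; this package treats the calliper procedure as the
  definition and offers exact matching only as an explicit flag.
* Whether sampling pooled the two prior years jointly or per year is not
  stated; years are pooled jointly here.
* The linear VA model's functional form (per-month OLS, no time term) is
  one reading of "a simple linear model"; alternatives would need the
  original data to distinguish.
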