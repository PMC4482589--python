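# Methods

This note records the statistical model, the main parameter choices and their
rationale, the scope of the synthetic-data generator, the numerical
implementation choices, and known limitations.

## Response transform

Annual area burned (hectares) is modeled on the natural-log scale. Years
with exactly zero mapped area receive a 10-ha offset **before** the log —
the offset is applied only to exact zeros, not added to every year, so
nonzero years are untouched (`log_transform_area`). The offset keeps
zero-burn years in the record at a value (ln 10 ≈ 2.3) far below any
burning year rather than dropping them; its magnitude is a detection-floor
convention, and results for records without zero years are independent of it.

## Regression model

Within any set of years, the model is ordinary least squares

    ln(area_t) = β0 + Σ_j βj · x_jt + ε_t,   ε_t ~ iid N(0, σ²)

with 1–3 climate predictors (`fit_ols`). Standardized slopes are reported as
βj · sd(x_j)/sd(y), computed with the same years as the fit, so they are
comparable across windows and metrics. Fitting requires n ≥ p + 3 and a
full-rank design; exact collinearity is reported as an error naming the
offending predictor pair. Multi-predictor models also report variance
inflation factors (VIF_j = 1/(1 − R²_j) from regressing predictor j on the
others, intercept included; flagged at VIF ≥ 10). Response normality is
screened with a Lilliefors test (Kolmogorov–Smirnov with estimated mean and
sd) whose null distribution is computed by seeded Monte Carlo (default
100,000 simulations, cached per sample size) rather than interpolated from
published tables.

## Coefficient of efficiency

For validation observations y and predictions ŷ,

    CE = 1 − MSE(ŷ) / MSE(validation-period mean)
       = 1 − Σ(y−ŷ)² / Σ(y−ȳ_v)²,

where ȳ_v is the mean of the *validation* observations. CE = 1 for perfect
prediction, 0 when the model only matches the validation mean, and negative
— unbounded below — when it does worse, the operational signature of an
altered relationship between calibration and validation eras. CE is defined
here for any validation set with at least 2 years and nonzero variance; a
zero-variance validation set is an error, not a silent NaN.

## Moving-window sweep

Windows are every contiguous 21-year span (odd width, so each window has a
center year); a 107-year record (e.g. 1902–2008) yields 87 windows, centered
1912–1998. Each window's model is validated on **all** years outside the
window (86 years), not on an adjacent block, so CE for every window refers
to a comparable validation set. The 21-year default trades locality in time
against the n ≥ p + 3 fitting floor and the variance of window statistics;
widths are configurable but must remain odd and shorter than the record.
Predictor sets are ranked by combining calibration accuracy and validation
skill across windows; both the median of per-window r²·CE products and the
product of the two medians are computed, with the former as the default
score (the two orderings can disagree; both are always reported).

## Null-model envelope

The null hypothesis is a single constant relationship: one full-record OLS
fit plus stationary noise. Realizations keep the observed predictor values
fixed and redraw the response as fitted values plus iid Gaussian noise at
the fitted residual sd (or bootstrap-resampled residuals). Each realization
is swept exactly like the data, and the central 95% (2.5th/97.5th
percentiles) of r², CE and each standardized slope is recorded per window
center. Observed trajectories leaving the envelope — especially jointly, on
several statistics, over consecutive centers — are inconsistent with a
constant relationship. Because window statistics at nearby centers are
strongly dependent (windows share up to 20 of 21 years), isolated
single-statistic exits occur by chance and should not be over-read; the
envelope is pointwise, not simultaneous. Default 10,000 realizations;
envelopes from fewer than 100 trigger a warning. A master seed spawns one
substream per realization (`numpy.random.SeedSequence`), so results do not
depend on evaluation order.

## Change points

Breaks in the mean burning level are located as slope changes in the
cumulative sum of ln(area): a continuous piecewise-linear function with k
free knots (hinge basis, knots midway between adjacent years) is fitted by
exhaustive search over all integer break combinations with a minimum segment
of 5 years, minimizing SSE exactly. The per-window Gram matrices are
assembled in O(1) from precomputed suffix sums, so the search is exact yet
fast (k ≤ 3 on century-scale records takes seconds). Segment slopes of the
cumulative fit equal segment mean annual ln(area). Each break's importance
is summarized by its SSE-improvement share (refit without that break);
requesting more breaks than the record supports yields near-zero shares and
a `degenerate` flag rather than an error. A discontinuous variant
(independent segments via dynamic programming) is available for comparison.

## Period comparison

Climate metrics are compared among the periods delimited by the change
points (a break year starts the new period; every period must span ≥ 10
years). The test is Kruskal–Wallis with tie correction, computed via the
rank-ANOVA identity H = (N−1)·SSB/SST, which remains defined (H = 0) when
all values are identical. Because annual series can be serially correlated,
lags 1–5 are screened against ±1.96/√n; if any lag is significant, the
p-value comes from a circular block bootstrap (block length = largest
significant lag, p = (1 + #{H* ≥ H})/(1 + n_boot), default n_boot = 5000)
instead of the χ² approximation. Significant omnibus tests are followed by
Tukey HSD on the rank-transformed values, summarized as a compact letter
display (groups sharing a letter are not distinguishable).

## Seasonal window optimization

Daily fire-danger or water-balance metrics are reduced to annual predictors
by a summary window inside the May 1 – Oct 1 fire season: either a
fixed-end window (mean over `length_days` ending at a given date, which may
reach before the season start) or a floating window (seasonal extremum of
the running `length_days` mean). The default candidate grid (9 lengths ×
(5 end dates + 2 floating statistics)) is searched by full-record r² against
the response, with ties broken toward shorter windows and fixed ends; a best
r² below 0.05 sets a `no_informative` flag. Window choice by in-sample r²
is deliberately simple and is made once, before the moving-window analysis.

## Synthetic-data generator — scope

`fireshift.simulate` generates records for *validating the methods*, not for
emulating any real fire regime. The default record is 107 years
(1902–2008) in three periods (boundaries 1943 and 1985) with

    ln(area) = β0_p + β1_p · climate_t + N(0, 1),   climate_t ~ iid N(0, 1),
    β0 = 8, β1 = 1  (full-record r² ≈ 0.5),

and 3% zero-burn years injected by zeroing the smallest generated areas (so
the pre-zero truth stays interpretable). Scenarios constrain which
parameters may vary by period: `constant_relationship` (nothing),
`climate_shift` (climate moments only), `altered_relationship` (regression
parameters only; the preset doubles β1 and raises β0 by one noise sd in the
final period), and `combined`. Climate may optionally carry mild AR(1)
autocorrelation (φ ≤ 0.25, enforcing the low-autocorrelation regime the
period-comparison screen expects of annual climate series). The generator
makes no claim about realistic fire-size distributions, spatial structure,
or predictor cross-correlations.

## Numerical choices

- OLS inside the sweep and envelope uses `numpy.linalg.lstsq`/pinv directly
  (statsmodels is used in the test suite as an independent oracle); the
  envelope sweep is vectorized across realizations since all share one
  design matrix per window.
- Calibration r² is clipped to [0, 1] against floating-point undershoot; CE
  is never clipped (its negative range is the signal).
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence`; pipeline stages draw from independent,
  stage-keyed substreams so rerunning one stage reproduces its stream.
- CSV writers emit floats at 6 significant digits with fixed line
  terminators so repeated runs are byte-identical.

## Limitations

- The envelope is pointwise per window center and statistic; no familywise
  correction is applied, and neighboring centers are highly dependent.
  Interpretation should weight sustained, multi-statistic excursions.
- The null model assumes homoskedastic noise and fixed observed predictors;
  it does not propagate predictor measurement error or heteroskedasticity.
- Change points detect shifts in the *mean* of ln(area); a pure slope
  (relationship) change without a level change is largely invisible to the
  cumulative-sum fit, by design — that is the envelope's job.
- The zero-burn offset (10 ha) is a convention; analyses of records with
  many zero years are sensitive to it and to the log-linear model itself.
- Window optimization selects by in-sample r² without cross-validation;
  with many candidate metrics this overfits and the chosen window should be
  treated as descriptive.
- Kruskal–Wallis compares distributions via mean ranks; with strong shape
  differences among periods, letters summarize stochastic ordering, not
  mean differences.
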