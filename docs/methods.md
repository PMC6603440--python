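# Methods

## The normative model

The pipeline is deliberately model-free. A normative percentile chart
(nomogram) for a regional brain volume is estimated by sliding an age
window of fixed *quantile* width along the age-sorted cohort: each
window holds ⌈f·n⌉ participants (f = 0.10 by default) and advances by
one sorted observation, so consecutive windows overlap maximally. The
nine reference percentiles (2.5, 5, 10, 25, 50, 75, 90, 95, 97.5) and
the mean/SEM of volume are computed within each window and indexed by
the window's median age. Because the age density is thin at the
extremes, the outermost windows span wider age ranges; this is a
property of the data that the method exposes rather than hides, and it
is why the nomograms are most trustworthy in the mid-age range.

Quantiles use linear interpolation between order statistics (the
"type 7" convention, numpy's default). For window sizes in the
hundreds the difference between quantile conventions is far below the
sampling noise; the convention is fixed and documented because the
windowed curves are compared against a brute-force order-statistic
oracle in the tests, where the convention matters exactly. One
consequence worth knowing: duplicating every observation changes
interpolated quantiles by up to one order-statistic gap, so quantile
"idempotence under duplication" holds only approximately.

Curves are smoothed by a Gaussian-weighted moving average with SD = 20
grid steps, truncated at ±3 SD, with weights renormalised at the
boundaries (no padding). Renormalisation keeps the smoothed curve
defined on the full grid. Since all curves share the same positive
weights, smoothing is monotone: quantile curves that do not cross
before smoothing cannot cross after it. Kernel SD 10 and 0 (identity)
are exposed for robustness checks, as is a fixed 5-year-bin variant of
the window construction.

Age-adjusted percentile tables subtract the sliding-window *mean* curve
(interpolated at each participant's age; the raw rather than smoothed
curve by default, switchable) from each volume and add the residual
back onto the cohort grand mean; the table is the set of empirical
percentiles of those adjusted values. Ages outside the window grid are
clamped to the nearest grid edge and counted in a warning.

## Preprocessing

Outliers are excluded per region when the MAD-denominated distance
|x − median| / MAD exceeds 5. The MAD is *unscaled* — no 1.4826
Gaussian consistency factor — because the cutoff is a visual convention
on the raw distance scale, not a z-score; the consistency factor is
available as an option. Masking is per-region, so different regions
may retain different participant sets. If the MAD is zero the distance
is undefined; nothing is excluded and a warning is emitted.

Confounds are removed by regression, not by ratio, because regional
volumes do not scale proportionately with head size. An OLS model of
volume on the confounds (scan date for scanner drift; the volumetric
head-scaling factor for head size; optionally age) yields slopes used
as corrected = volume − Σ_c slope_c (x_c − reference_c). References
default to confound means — which preserves the cohort mean — except
head scaling, whose reference is the fixed neutral constant 1.29874 so
that published correction slopes b remain portable: a query volume is
corrected by subtracting (h − 1.29874)·b. Scan-date drift is a single
linear term fitted per region; whether a real pipeline would fit it
globally or per region is an open choice, and per-region fitting is
used here because it is the more conservative (self-contained) option.

## Trajectory inflection and the permutation peak test

A region's trajectory relative to global atrophy is the windowed,
smoothed curve of V_region / (V_greymatter − V_region). Its peak age —
reported as the age span of the maximising window, ties broken toward
the youngest window — marks the transition from slower-than-global to
faster-than-global decline. Numerical differentiation (central
differences on the median-age grid) locates the steepest-decline bin;
pointwise confidence bands come from a participant-resampling bootstrap
(windows and smoothing rebuilt per replicate; tied grid ages produced
by resampling are collapsed by averaging before differentiating).

The sex difference in peak-ratio age is tested by permutation: sex
labels are shuffled *within 1-year age bins* (a label permutation, so
per-bin sex counts are preserved and the age distributions of both
pseudo-sexes match the originals), and both sex curves, including the
windowing and smoothing, are recomputed per permutation — the
conservative choice compared with permuting pre-smoothed residuals.
The two-sided p-value is (#{|null diff| ≥ |observed|} + 1)/(n_perm + 1);
the add-one correction avoids p = 0 at finite n_perm, and the raw
proportion is available as an option. Across regions p-values are
Benjamini–Hochberg adjusted. The default n_perm = 5000 resolves
p ≈ 0.001; the calibration simulations in the tests use n_perm = 199
with 200 replicates, which is the smallest design that still bounds the
type-I rate usefully at α = 0.05.

## Joinpoint regression

Mean volume per 1-year, non-overlapping age bin (empty bins dropped
with a warning) is fitted with continuous piecewise-linear segments on
a hinge basis [1, x, (x−τ₁)₊, …], so each hinge coefficient is directly
a slope change Δm. Candidate joinpoints sit on the observed bin
mid-ages (grid search over all admissible placements; a placement is
reported as its 1-year bin). Admissibility: no joinpoint within two
data points of either end, at least two data points strictly between
consecutive joinpoints, and at least seven data points per joinpoint,
capping k at 4 for the 35-bin series a 45–80-year cohort produces.
Bins are unweighted by default (weighting by bin n is an option);
per-bin counts vary, but the unweighted fit matches the convention of
trend-analysis practice for this model.

Model selection is sequential: to test k vs k+1 joinpoints the
statistic (RSS_k − RSS_{k+1})/RSS_{k+1} is compared with its Monte
Carlo null obtained by permuting the residuals of the k-joinpoint fit
(uncorrelated-errors assumption) and refitting both models on each
permuted series; the ladder stops when a step's p-value exceeds
α/k_max (Bonferroni over the ladder). Permutation refits are made
cheap by precomputing an orthonormal basis per candidate placement, so
each permuted series costs one matrix product. Residual permutation is
one of several resampling schemes used for this selection problem; it
is implemented and labelled as such.

Slope-change inference uses the OLS covariance at the selected
placement: SE(Δm) from σ²(XᵀX)⁻¹ with σ² = RSS/df and df = n_bins −
2(k+1) — each joinpoint consumes two parameters (position and slope),
which for 25 usable bins and one joinpoint gives the conventional 21
degrees of freedom. Joinpoint confidence intervals invert an F
comparison: a candidate bin is inside the 95% CI when the best fit
constrained to place the joinpoint there is not rejected against the
unconstrained optimum at F(1, df); the CI is the age span of accepted
bins and always contains the point estimate.

## Percentile lookup and calibration

A lookup locates the query age on the nomogram grid (linear
interpolation between flanking columns; nearest-window is switchable
since either convention is defensible), then interpolates the
percentile linearly in volume between the flanking quantile curves.
Below the 2.5th or above the 97.5th curve the answer is censored
("<2.5" / ">97.5") — tail shape beyond the outermost estimated curve
is never extrapolated, a clinical-safety choice. Ages outside the grid
clamp to the nearest column and the answer is flagged "extrapolated".
cm³ inputs are converted (×1000) since clinical reports quote cm³ while
the tables are in mm³. Head-size correction inside the lookup requires
a nomogram built with head-scaling correction; mixing conventions (a
corrected query against an uncorrected nomogram, or vice versa) raises
an error rather than returning a silently wrong percentile. Nomograms
store their full correction model (slope and reference per confound),
so held-out volumes can always be corrected consistently.

The calibration audit runs every member of a held-out cohort through
the lookup. If the nomogram describes the population, percentiles are
uniform; censoring leaves the conditional law of the non-censored
percentiles uniform on (2.5, 97.5), which is tested by KS after
rescaling. One subtlety: the percentile of a held-out member is its
rank within the *estimated* nomogram, making this a two-sample
comparison (held-out members vs the training sample behind the
curves). The one-sample KS null would over-reject — its D statistic is
inflated by roughly √2 even under perfect calibration, which simulation
against known true curves confirms — so the audit p-value uses the
two-sample null with effective n = n_train·n_test/(n_train + n_test),
n_train being recorded in the nomogram.

## The synthetic cohort generator

The generator emulates the statistical structure of a large
single-scanner imaging cohort of generally healthy adults aged 45–80:

- **Counts and ages.** Defaults 10,463 female / 9,330 male. Ages are
  triangular on [45, 80] with sex-specific modes 62 (F) and 66 (M) —
  thin tails and sex mean ages ≈ 62.3 / 63.7 years. The true empirical
  age density of such cohorts is not published; the triangular shape is
  a stand-in with the right qualitative behaviour, not a claim.
- **Volumes.** Nine generated region columns (left/right hippocampus,
  six temporal-lobe regions, total grey matter; bilateral hippocampus is
  the L/R sum). Each volume is a sex-specific baseline plus a
  continuous hinge in age (slope changes, intercept continuous — the
  same segment model joinpoint regression fits), a head-scaling term,
  linear scanner drift, covariate shifts and Gaussian noise.
  `baseline_volume`/`baseline_sd` are the target *marginal* mean and SD
  after outlier exclusion: every systematic term is analytically
  centred (triangular-density quadrature for the age hinge) and its
  variance subtracted from the noise budget, so the published summary
  means/SDs hold by construction rather than by tuning. A
  `sd_is_noise` switch makes `baseline_sd` the residual noise SD
  directly, which the tests use when an exact noise level is needed.
- **Trajectory geometry.** Female hippocampal hinge at 64.5 years with
  a bilateral slope change of −32.44 mm³/yr, male at 63.5 with
  −26.45 mm³/yr (split evenly across hemispheres); total grey matter
  declines linearly. Pre-hinge slopes (−10 / −15 mm³/yr bilateral) are
  not published and were chosen to make hippocampal decline clearly
  slower than global decline before the hinge and faster after it.
- **Hemispheres.** Left/right hippocampal noise shares a common
  component (correlation 0.8), with a right-larger-than-left offset of
  88 mm³; per-hemisphere SDs are scaled so the L/R average reproduces
  the printed SD of the average.
- **Head size.** Head scaling ~ Normal(1.29874 ± 0.065, 0.1), females
  higher (smaller heads). Slopes b are the published correction values
  for left/right hippocampus and total grey matter and ≈ −0.55× the
  mean for the other regions. At offset 0.065 the head-scaling slopes
  explain essentially the whole raw sex gap in grey-matter and
  hippocampal volume, so corrected sex differences are near zero — the
  pattern corrected comparisons of such cohorts show.
- **Drift.** −0.2% of the region mean per year across a 4-year scan
  window; the drift magnitude is not published and only its linear form
  matters downstream.
- **Covariates.** Hypertension (prevalence 0.27), smoking
  (never/previous/current 0.60/0.35/0.05), education (lower 0.55), BMI
  ~ Normal(27, 4.5), handedness (right/left/ambidextrous
  0.89/0.10/0.01). Effects are specified on the Hedges' g scale *as an
  analyst measures them*, i.e. relative to the residual SD after
  deconfounding (hypertension g = −0.17 on grey matter, −0.06 on
  hippocampus; smoking current vs never −0.33 / −0.15; education
  −0.07 on hippocampus; BMI as Pearson r = −0.11 / −0.03).
- **Outliers.** 0.7% of rows per region, displaced ±8 marginal SDs with
  random sign so the median stays unbiased — producing per-region
  exclusion counts of the observed order (≈140 per hippocampal
  hemisphere at full cohort size) under the MAD > 5 rule.
- **Randomness.** One seed feeds a seed-sequence splitting scheme with
  a child stream per column and purpose, so generation is
  bit-reproducible and adding a column never perturbs the others.

What the generator does **not** emulate: segmentation error structure,
site/scanner random effects, longitudinal repeat scans, non-Gaussian
volume distributions beyond the injected outliers, and any dependence
of covariates on age. Passing tests therefore demonstrate that the
pipeline recovers known structure of this idealised form; they do not
validate the method against the messier failure modes of real imaging
tables.

## Problem sizes used in tests and the acceptance script

Simulation-based checks are scaled to single-CPU runs: joinpoint
recovery and type-I use 100 replicate 35-bin series with n_perm = 199;
permutation-test calibration uses 200 replicate cohorts of 3,000 with
n_perm = 199, and the power check one cohort of 20,000 with
n_perm = 999; the percentile audit splits a 4,000-participant cohort in
half; the end-to-end check runs the full default 19,793-participant
cohort. These sizes give each check comfortable resolution at its
threshold while keeping the whole suite in the minutes range.

## Known limitations

- Joinpoint positions are restricted to bin mid-ages (grid search);
  continuous-position refinement is out of scope, so a true change
  point between bins is localised to its bin.
- The sequential permutation selection assumes uncorrelated bin errors;
  strong residual autocorrelation would inflate the selected k.
- The nomogram edges are estimated from wide, thinly-populated windows;
  lookups there are flagged but still less reliable.
- Percentile interpolation is linear in volume between the nine curves;
  between widely separated curves (25th–50th) this introduces a small,
  bounded distortion relative to the true conditional law.
- The permutation peak test's power depends on how sharply the ratio
  curve peaks; for nearly flat post-peak trajectories the peak age is
  weakly identified and the test is conservative.
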