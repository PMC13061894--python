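# Methods

This note documents the models, estimators and numerical choices behind
`gestaltfbm`, and what its synthetic-data generators do and do not
emulate.

## Scientific setting

Gestalt cues — symmetry, closure, convexity — bias which regions of a
textured image are perceived as *figure* and which as *background*.
Two linked measurements are modelled here:

1. **Behavior.** The perceived contrast (PC) of a Gabor probe is higher
   on figure regions.  In a two-alternative forced-choice (2AFC)
   contrast-discrimination task, a reference Gabor at 30% Michelson
   contrast is compared with a variable test Gabor; the test contrast
   at criterion accuracy (the contrast discrimination threshold, CDT)
   measures the perceived contrast of the reference.
2. **Neurophysiology.** Multi-unit activity (MUA) in visual areas V1
   and V4 is elevated when the receptive field (RF) lies on a figure
   region — figure-background modulation (FBM).  A Naka-Rushton
   contrast-response function fitted per recording site can be inverted
   to convert the FBM-induced change of the Gabor-evoked response into
   an equivalent contrast change, predicting the behavioral PC shift.

## Stimuli (`stimgen`)

Strips are 7 d.v.a. high, span the screen width, and contain six
texture regions (three figure, three ground, average width 5 d.v.a.)
separated by 0.2-d.v.a. black lines.  Textures are white line elements
(0.04 x 0.8 d.v.a., orientation 45 or 135 deg, alternating by 90 deg
between adjacent regions) placed by seeded Poisson-disc sampling
(minimum spacing 0.42 d.v.a.) and clipped at region boundaries, so
figure and ground textures are statistically identical.

The exact region outlines per cue are not prescribed by any published
coordinates, so the package defines a **versioned parametric outline
family** (`OUTLINE_VERSION = 1`), designed so that each cue is carried
in isolation and verified by an independent geometric oracle
(`check_cue_properties`):

* *convexity* — parabolic boundaries bulging away from the figure
  (figure convex, grounds concave).  The parabola vertices of the left
  and right boundary are offset vertically in opposite directions,
  which destroys mirror symmetry without increasing the bulge;
* *symmetry* — sine-wave boundaries mirrored about each figure's
  vertical axis (different waves per figure, so grounds are
  asymmetric); the waves are neither convex nor closed;
* *closure* — independent waves on the two sides plus black cap lines
  at the strip's top and bottom across the figure regions only, so the
  figure outline is a closed contour while grounds stay open;
* *all cues* — symmetric parabolic barrels with closure caps;
* *ambiguous* — straight vertical bands.

All boundary excursions stay below 0.5 d.v.a. so that an RF centered on
any region keeps the required 2-d.v.a. distance from the nearest
boundary.  The oracle checks mirror-symmetry by the IoU of a region
mask with its reflection about the vertical centroid axis (threshold
0.95), convexity by the ratio of mask area to convex-hull area
(threshold 0.97), and closure by verifying that every outside neighbor
of the region mask is an edge pixel.

Luminance images are rendered on a 2x supersampled grid and box
downsampled, which anti-aliases the thin texture lines; label masks are
computed analytically at output resolution.  Gabor probes (3
cycles/deg, Gaussian SD 0.33 deg, 2-deg aperture, vertical) are *added*
to the texture luminance.  Because the Gaussian envelope attenuates the
sinusoid's nearest trough, a raw `L0(1 + c·env·cos)` patch would have a
measured Michelson contrast ~6-8% below its nominal `c`; the modulation
amplitude is therefore rescaled from the rendered pixels so that the
patch's measured `(Lmax-Lmin)/(Lmax+Lmin)` equals the nominal contrast
exactly.  Negative contrasts give the exact negative modulation, making
embedding a signed inverse (used as a property test).  After addition
the image is clipped to the display range; a warning is emitted if more
than 0.1% of aperture pixels clip (clipping can be disabled).

## Behavioral designs and estimators (`psychophysics`)

**2-down/1-up staircase.**  The rule acts on the test-reference
contrast *difference*: two consecutive correct responses shrink it, one
error grows it.  Test contrasts are bounded to 22-38% with steps of 2%
until the first reversal, 1% until the second and 0.5% afterwards;
ascending staircases start at the lower bound, descending at the upper
(the exact start values are a package choice — only "lower/higher" is
prescribed).  Reversals are counted on actual contrast-movement flips;
a move clipped at a bound that changes nothing is not a direction
event.  The classical fixed point of this rule is an accuracy of
sqrt(0.5) ~ 70.7%; the procedure is often described as converging to
75%.  The implementation follows the rule as written and reports the
empirical convergence accuracy.  Note that the fixed-point argument
assumes steps small relative to the psychometric spread; with the 0.5%
terminal step, observers with very steep slopes (10-90% width of ~2%
contrast or less) converge to measurably higher accuracy, so the
calibration tests use an ideal observer with slope 1.0 per % contrast.

**CDT and perceived contrast.**  The CDT of a staircase is the mean
test contrast of its last 3 non-easy, non-aborted trials; per-session
CDT estimates are averaged with equal weights.  The PC shift is
`dPC = 30 - sqrt(CDT_asc * CDT_des)`; the geometric mean accounts for
Weber's law (performance is better on ascending staircases, where the
average contrast is lower).

**QUEST.**  A grid posterior over the threshold of an assumed logistic
psychometric function in linear contrast (guess 0.5, assumed lapse
0.02, assumed slope 0.5 per % contrast, Gaussian prior mean 30 /
SD 10, grid step 0.05%).  Each trial is placed at the contrast where
the assumed function at the posterior-mean threshold reaches the
criterion (default 75% correct); contrasts are restricted to 10-50%
and 15% easy trials at 10% or 50% are interleaved (all trials update
the posterior — easy trials are informative Bernoulli data under the
model).  Posterior mass concentrating at a range edge raises a
divergence flag, never a silent estimate.

**Constrained psychometric fit.**  Responses ("chose test") are binned
into 29 contrast bins over 0-60% and fitted jointly across conditions
with `psi(x) = gamma + (1-gamma-lambda) * logistic(beta (x - alpha))`:
one threshold `alpha` per condition, with slope, guess rate and lapse
rate shared (parallel shifts only) and `gamma, lambda` constrained to
[0, 0.4] (the upper asymptote is `1 - lambda`, i.e. lapses are errors
at theoretically infinite contrast).  `x` is the test contrast for
PC-style fits (the threshold is then the point of subjective equality,
i.e. the perceived reference contrast) and may instead be a signed
contrast difference for threshold-style fits (`x_col` argument).  The
likelihood is maximized by L-BFGS-B with an analytic gradient and a
small multi-start over the slope; empty bins are skipped.

**Bootstrap null.**  For each cue, surrogate correct-counts at every
contrast bin are drawn from a binomial whose success probability is
the pooled probability across the figure and ground conditions,
keeping the original trial counts; the model is refit (warm-started at
the observed solution) and the two-tailed p-value is the plain
proportion of unsigned null differences `alpha_fig - alpha_bg` at
least as large as the observed one (minimum attainable p is
`1/n_boot`; default `n_boot = 1000`).  Refit failures are counted and
more than 5% aborts the procedure.

**Figureness.**  The percentage of trials on which the reported role
matches the cued role; 50% is chance.  Per cue, subject scores are
tested against 50% with a right-sided Wilcoxon signed-rank test,
Bonferroni-corrected over the number of cues tested (config-exposed).

## MUA preprocessing (`ephys_preproc`)

Broadband signals (24414.0625 Hz, the TDT rate family) are band-pass
filtered 500-5000 Hz (4th-order Butterworth; the order is a package
choice), full-wave rectified, low-pass filtered at 200 Hz, decimated by
exactly 32 to 763.0 Hz, notch filtered at 50 Hz (Q = 10) and low-pass
filtered with a 5th-order Butterworth at 40 Hz.  The notch is applied
after decimation, consistent with its description as acting on the MUA
signal; all filters are zero-phase (forward-backward) so FBM window
statistics are not latency-distorted.

Baseline correction subtracts, from each trial's whole trace, a robust
locally-weighted regression (lowess, 30% span, 5 robustifying
iterations) of the per-trial baseline mean (-100-0 ms) over the trial
sequence.  statsmodels' lowess is local *linear* with tricube weights
and bisquare robustification; a local quadratic was considered but the
linear smoother already meets the drift-removal and outlier-robustness
contracts.  With fewer than 10 trials the smoother degenerates and a
per-trial mean subtraction is used (with a warning).

Normalization divides all trials by the site's peak response: the
maximum, within 30-100 ms, of the mean across well-centered trials
after a 20-sample moving average.  Activity is then in normalized
units (n.u.; 1 = peak response).  Sites with a non-positive peak are
excluded with a reason code; normalization is idempotent.

QC chain (all thresholds in `QCConfig`): recording days with SNR < 0.5
are excluded per site (SNR = peak estimate / SD across trials of the
baseline mean); surviving days must correlate with the across-day mean
response above r = 0.85; sites need an overall SNR > 1 and an RF
center within 1 d.v.a. (horizontal) and 2 d.v.a. (vertical) of the
probed region center.  Time axes are in ms relative to texture onset
and all analysis windows are closed intervals inclusive of both edges.

## RF mapping (`rf_mapping`)

Bar sweeps (15.75 deg/s, four cardinal directions) are converted from
time to space via the bar speed (an optional latency correction,
default 0 ms, shifts the apparent center along the motion direction);
the mean response per direction is fitted with a 1-D Gaussian and the
RF borders are its 2.5th/97.5th percentiles (center +- 1.96 sigma).
Opposite directions are averaged per axis; `SNR_RF` (Gaussian peak /
baseline SD across trials) below 2 flags the site.  Grid protocols
(21 x 21 one-degree squares) are fitted with an axis-aligned 2-D
Gaussian by bounded least squares with moment-based multi-starts;
sites with r^2 <= 0.4 (1 - SS_res/SS_tot over grid cells) are
excluded.  RF size conventions: `fwhm = 2.35 sigma` with sigma the
geometric mean of sigma_x and sigma_y; the bar method reports
sqrt(area) of the border rectangle.  Aggregate RFs average centers and
sizes of included sites on an array.

## FBM statistics (`fbm_stats`)

Site-level FBM is the figure-minus-ground difference of window-averaged
responses, tested with a classical equal-variance independent t-test;
two single-tailed tests at alpha = 0.05 classify sites as enhanced /
suppressed / ns.  Window conventions: texture windows start at 100 ms
(V1) or 50 ms (V4, where FBM arises earlier) and end 40 ms after Gabor
onset (240 or 340 ms); Gabor windows are 40-140 ms after Gabor onset.

Population tests weight each site by the inverse of its animal's site
count, normalized to sum to the number of sites, so each animal
contributes equally; the weighted paired t uses the weighted mean and
variance with df = n_sites - 1 and reduces exactly to the classical
test under uniform weights.  The cue effect on FBM is tested by a
weighted one-way fixed-effects linear model (WLS F-test); the choice of
site as the unit of analysis is a documented package decision.
Area comparisons use per-cue 2 x 2 Pearson chi-square tests (1 df, no
continuity correction) on the enhanced-vs-not classification, with a
Fisher-exact fallback for expected counts below 1, plus independent
t-tests on FBM magnitude.  Shape selectivity is assessed with one-way
ANOVAs over the region-shape identity, separately for figure and for
ground trials (disjoint trial sets), isolating shape tuning from FBM.

## Contrast linking (`contrast_link`)

Gabor-window responses at varying test contrast are grouped into 20
equal-count bins (quantile edges; bin contrast = mean contrast of its
trials) or left at the 31 fixed levels for constant-stimuli designs,
then fitted with `y(x) = b + a x^n / (x^n + c50^n)` by bounded least
squares (b in [0,1], a in (0,3], c50 in (0.01,1], n in [0.5,5]) with a
multi-start grid over (c50, n) — the least-squares surface is shallow
along that ridge.  Sites are included when r^2 > 0.5.  The inverse
`x(y) = ((y c50^n - b c50^n)/(a - y + b))^(1/n)` is defined for y
strictly inside (b, b + a); out-of-range responses yield NaN and are
excluded from means with an audit count, never clamped.  Per-site
predictions map the figure and ground Gabor responses (same 30%
physical contrast) through the inverse; the cue-level prediction is
the mean per-site delta over included sites (per-cue by default; a
pooled mode is available).

## Synthetic data (`synthetic_data`)

The generators provide the statistical structure the analyses assume,
with ground truth stored alongside every dataset:

* **Observer** — logistic 2AFC decision on the *perceived* contrast
  difference; a Gabor on a figure region is perceived
  `+figure_bias/2` higher, on a ground region `figure_bias/2` lower.
  In the human staircase design the variable test Gabor sits on the
  Gestalt strip; in the monkey designs the constant reference does, so
  in both cases the estimators recover `+figure_bias` for figures.
  Guess/lapse rates are bounded by [0, 0.4]; a spatial response bias
  can override the decision with a fixed-side choice (reproducing the
  unusable strongly-biased animal as a degenerate case).
* **Sessions** — closed-loop with the package's own staircase/QUEST
  engines; easy trials at 10% (staircase, at the 22/38% bounds) or 15%
  (QUEST, at 10/50%); constant-stimuli designs draw from 31 fixed
  levels spanning 10-60%.
* **MUA** — per trial: baseline + onset transient (alpha kernel
  peaking at 45 ms plus a small sustained component) + FBM term on
  figure trials + `crf(contrast)` x Gabor transient + Gaussian noise
  (optional AR(1)) + slow across-trial drift (OU process) and/or
  white per-trial baseline jitter calibrated to a target SNR.  FBM
  time courses: *sustained* (sigmoidal rise at ~110 ms persisting
  through the Gabor epoch) or *transient-reversing*
  (difference-of-exponentials transient, onset 100 ms / rise 25 ms /
  decay 70 ms, minus a slower sustained component — positive in the
  texture window, negative by Gabor onset).  Both patterns live in one
  parametric family.  Trial counts per condition default to 40 per
  site (not reported for the original recordings; config-exposed, and
  chosen for reasonable power at the default noise level).  The
  default per-cohort FBM amplitude is 0.05 n.u., which keeps the
  FBM-induced Gabor-response change well inside the invertible range
  of typical contrast-response functions.
* **RF protocols** — Gaussian-profile responses for bar sweeps (with a
  100-ms pre-stimulus baseline) and 21 x 21 grids, plus noise.

What the generators do **not** emulate: spiking point processes,
LFP/spectral structure, eye movements and fixational confounds,
adaptation and serial dependence, inter-areal latency differences, and
realistic correlated noise across sites.  Passing tests therefore
demonstrate that the estimators are correct and calibrated under the
assumed statistical structure, not that the preprocessing would be
robust to every pathology of real recordings.

## Problem sizes used in the validation suite

Simulation scales are chosen to make the statistical checks decisive
while keeping the suite quick to run: bootstrap calibration uses 200
null datasets x 500 replicates (11 contrast levels x 30 trials x 2
conditions each); QUEST calibration 500 runs of 100 trials; staircase
calibration 120 sessions; FBM null calibration 1000 sites; sign
concordance 50 runs per cohort type with 8 sites each.  The
acceptance script (`scripts/acceptance.py`) recomputes the QUEST
criterion accuracy (500 runs) and the chance-level figureness score
(10,000 trials) from scratch for any seed.

## Known limitations

* The outline family is one concrete realization of the cues; the
  oracle-checked properties (not the exact shapes) are the contract.
  Alternative families can be registered under a new
  `OUTLINE_VERSION`.
* The weighted "linear model" for the cue effect is a fixed-effects
  WLS; a mixed model with animal as a random effect would be the
  natural extension when more animals are available.
* QUEST assumes a logistic in linear contrast; strongly Weberian
  observers would call for a log-contrast parameterization (the
  config exposes the assumed family's parameters but not its shape).
* The bootstrap p-value is a plain proportion with resolution
  `1/n_boot`.
* `predict_delta_pc` treats sites as exchangeable; no hierarchical
  shrinkage across sites is applied before averaging.
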