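# Methods

This note documents the models and procedures implemented in `xylemae`, the
conventions adopted where the underlying analysis is under-determined, and
the limits of what the synthetic validation shows.

## 1. Data model

An experiment is a time-ordered table of AE hits (seconds since start +
the 18 waveform parameters an AE acquisition system exports: RISE, COUN,
ENER, DURATION, AMP, AFRQ, RMS, ASL, RFRQ, IFRQ, SIGSTRNGTH, ABSENERGY,
FREQPP1–4, FRQC, PFRQ), a schedule of non-overlapping windows (4-min scan
rotations and inter-run breaks), and one µCT embolism count per window.
Hits are assigned to windows half-open, [start, end): a hit exactly on a
boundary joins the window it starts. Hits falling in schedule gaps (e.g.
acquisition paused during leaf excision) are collected as orphans and
excluded from training. The 28 dB noise floor is applied as a strict
inequality — a hit at exactly the noise level is noise. The acquisition
band-pass (20–1000 kHz) is hardware metadata and is never recomputed.

## 2. Count-weighted LDA

Two-class generative model with shared covariance on the six selected
parameters (AMP, COUN, DURATION, SIGSTRNGTH, ABSENERGY, FREQPP2), fitted
from window summaries only (see README for the estimator). Conventions:

* **Complement weights.** Non-embolism events are not observed separately;
  the background weight of window d is its hit count minus its µCT count.
* **Covariance.** Σ is the window-size-weighted average of within-window
  covariances (ddof 0). A class-weighted alternative is available
  (`covariance_weighting="class"`).
* **Prior.** The global count ratio Σn1/Σm. The analysis never states a
  prior separately, and any constant prior only shifts the posterior's
  intercept.
* **Bias, deliberately kept.** Window means mix both classes, so the
  weighted estimator shrinks µ̂₁ and µ̂₀ toward each other in proportion to
  the within-window mixing. This is faithful to the estimator as used in
  practice, and it is why per-hit posteriors stay far below 1 while window
  posterior sums remain approximately calibrated (the posterior's total mass
  equals the prior mass). An unbiased alternative that solves the two-point
  mixture moment equations and removes the between-class inflation from Σ is
  available (`moment_corrected=True`, default off).
* **Regularization.** When Σ̂ is near-singular (non-positive or condition
  number > 1e12), a relative ridge of 1e-8 · trace(Σ)/6 is added to the
  diagonal, escalated deterministically if needed.
* **Features are used raw.** Σ absorbs scale; standardization would change
  nothing in the posterior.
* **Validation.** Leave-one-window-out: refit on all other windows, sum the
  held-out window's posteriors, compare to its µCT count. Folds whose
  training windows carry no positive count cannot identify the embolism
  class; they are flagged and fall back to prior × window size. The total
  prediction is the sum of raw posterior sums (not per-window rounded
  values).

With every window pure (count 0 or count = size) the estimator reduces
exactly to textbook supervised LDA; the test suite checks this against
scikit-learn to machine precision, and checks the posterior against direct
evaluation of the two normal densities.

## 3. Exploratory screening

PCA standardizes columns first (the 18 parameters span orders of magnitude
across units); constant columns are dropped with a warning. Correlations are
Pearson. Per-window histogram thresholding retains exactly the window's
count of hits with the largest parameter values, ties broken toward earlier
timestamps.

ROC curves are supervised by counts, not labels: at each cutoff the true
positives within window d are capped at its µCT count, the remainder being
false positives. Two consequences worth knowing: (i) a perfectly separating
score reaches tpr = 1 at fpr = 0 exactly when the retained totals match the
µCT total; (ii) with heavily mixed windows the cap mechanically lifts every
curve above the diagonal (AUC ≈ 1 − ᾱ/2 with ᾱ the embolism fraction of
embolism windows even for a label-independent score), so single-parameter
and posterior ROCs should be compared with each other, not against an
absolute scale. The label-independence → diagonal property holds for pure
windows, and that is how the suite tests it. An uncapped variant (every hit
of an embolism window counts as a potential true positive) sits behind
`capped=False`.

## 4. µCT detection

Per consecutive stack pair: median projection of the 50 mid-centered slices
(robust to single-slice artifacts; mean available by flag) → crop to the
Otsu-foreground bounding box (+2 px margin, box fixed by the earlier image
of each pair so coordinates stay comparable) → 3×3 planar median filter (the
projection already pooled the z-direction) → registration → difference
(before − after, so embolization is a positive peak) → maxima.

Registration estimates translation + isotropic scale by Nelder–Mead on the
mean squared intensity difference, seeded by phase cross-correlation, and is
guaranteed never to return a transform worse than identity (falling back to
identity with a warning flag). Elastic contour matching used for living
tissue is deliberately reduced to this similarity family — a fidelity
reduction appropriate to bench-stable stems whose inter-scan motion is
rigid drift.

Maxima detection merges contiguous super-threshold regions into one event at
the region's intensity-weighted centroid (the Fiji "Find Maxima" convention
of merging maxima within a contiguous area; a flat-topped vessel disc is one
event, not several), with a 30-grayscale threshold and a 3 px minimum
separation between events. On noise-free planted data with transition depth
above the threshold, precision and recall are exactly 1 by construction, and
the suite asserts it.

## 5. Vulnerability curves

* **Cumulation.** Event times (unit weight) or per-hit posteriors are summed
  and averaged over 10-min bins; the bin value is the exact time average of
  the running-sum step function within the bin (not a resample at bin ends —
  both readings were considered; the average is the implemented one).
* **Derivatives.** Iterated centered windowed least-squares slopes
  (Savitzky–Golay, polynomial order 1, derivative 1); an order-k derivative
  is k passes with the same window. Exact for polynomials through the
  requested order (the cubic check: d³(a·t³)/dt³ = 6a), validated against an
  independent smoothing-spline derivative on noisy sigmoids. Default windows:
  15 min for AE activity (first derivative), 48 h for the third derivative.
* **Endpoint rule.** The acoustic curve's endpoint is the first local
  maximum of the third derivative after the peak of AE activity. A still
  non-decreasing third derivative at the series end means dehydration
  stopped before all conduits emptied; the endpoint is then undefined — a
  valid outcome, not an error, and the expected one when a fraction of
  vessels stays water-filled.
* **Percentage rescaling.** end% = 100 · (native + detected)/total — e.g.
  (541 + 518)/1100 → 96 % and (541 + 457)/1100 → 91 %. The native census
  raises only the ceiling; curves start at 0. The alternative convention
  starting at the native percentage is available (`start_at_native=True`,
  default off). Vulnerability levels (12/50/88/100) are absolute percentages
  of the axis, not fractions of the ceiling — a 91 %-ceiling curve has an
  88 % value but no 100 % value.
* **Stress–strain mapping.** ψ_x point measurements against dendrometer
  strain are fitted with a continuous three-segment linear model; the two
  breakpoints are found by exhaustive search over the observed strain
  quantiles (default 25 levels) minimizing the residual sum of squares,
  with segment slopes by least squares and per-segment R² reported.
  Candidates leaving fewer than two points in a segment are skipped.
  Breakpoint resolution is therefore the quantile-grid spacing. Strain
  outside the fitted range is extrapolated linearly with a warning.
* **Vulnerability values.** The percentage series is made monotone
  (isotonic along decreasing ψ), a smoothing spline of percent vs ψ is
  fitted with stiffness chosen by generalized cross-validation, and each
  level crossing is located by bisection on the monotone fit (linear
  interpolation fallback where the spline is locally non-monotone or the
  series is too short). Curve comparison interpolates both curves onto a
  common ψ grid over their overlap and reports the absolute-difference
  series, its mean and maximum, and the relative difference of the 50 %
  points rounded to integer percent.

## 6. The synthetic generator

The generator emulates a combined AE/µCT dehydration campaign and is the
ground truth for every test. Defaults describe a realistic three-day bench
run: 72 h duration; 6 × 4-min rotations per scan run with 6-min breaks
during the day (07–22 h clock time) and 30-min at night; 1100 vessels with
541 natively embolized; an inhomogeneous Poisson process of embolism
arrivals with expectation 457, sampled by thinning against a hazard
proportional to the time derivative of a logistic embolism course in
ψ_x(t) (midpoint −2.3 MPa, scale 0.5 MPa); ~25 400 expected background hits.

Choices that matter:

* **Background tracks dehydration.** Non-embolism AE (fibers, parenchyma,
  bark) dries on the same schedule as the vessels, so background intensity
  is a 20 % constant floor plus an 80 % component proportional to the
  embolism hazard's shape. This is what makes unfiltered acoustic curves
  resemble µCT curves in real experiments, and the generator reproduces that
  behaviour rather than assuming uniform noise.
* **Features.** Embolism and background hits draw the six discriminative
  parameters from N(µ₁, Σ) and N(µ₀, Σ) with a shared covariance
  (positively correlated shape/energy parameters, FREQPP2 mildly
  anti-correlated with AMP/COUN); a 2 % heavy-tailed contamination fraction
  of background hits emulates the outliers visible in PCA of real data.
  Class means were chosen so the analysis reproduces the qualitative
  behaviour of real campaigns — low per-hit posteriors, calibrated window
  sums, posterior ROC dominating single parameters — and so that the
  physically non-negative parameters (AMP, DURATION, partial powers) are
  essentially unaffected by boundary clipping; COUN and the energy
  parameters are left unclipped continuous Gaussians, a deliberate artifact
  of the Gaussian model. The twelve remaining table columns are independent
  log-normal nuisance so the full 18-column schema is exercised. Partial
  powers FREQPP1/3/4 split the residual of FREQPP2 on a Dirichlet simplex so
  the four always sum to exactly 100 %.
* **Consistency by construction.** Every embolism hit's timestamp falls in a
  schedule window and increments that window's count, so window counts equal
  hidden labels exactly. The strain trace follows a smooth monotone
  shrinkage, ψ_x(t) follows the configured three-segment model exactly when
  measurement noise is disabled (ψ point noise defaults to 0.05 MPa,
  the realistic pressure-chamber repeatability).
* **Images.** 256×256 8-bit-range stacks, vessels as discs of radius 2–6 px
  (grey 140, embolized 30, matrix 90) — arbitrary rendering constants, not
  physical claims; configurable per-slice noise and rigid inter-stack drift;
  exactly the window's count of vessels switches grey→black between
  consecutive stacks.
* **Seeding.** One master seed; per-component child generators derived via
  `SeedSequence.spawn`, so experiments are bitwise reproducible.

**What passing tests show — and don't.** The generator satisfies the
classifier's model assumptions by construction (shared-covariance Gaussian
classes, Poisson arrivals, rigid image drift, exact count labels). Passing
the end-to-end checks therefore demonstrates that the pipeline's estimators,
detectors and curve constructions are correct and internally consistent, and
that the three vulnerability-curve routes agree when the model holds. It
does not demonstrate robustness to what real experiments add: non-Gaussian
and drifting AE feature distributions, attenuation that changes with water
content, elastic (non-rigid) tissue deformation between scans, beam-
hardening and reconstruction artifacts, or µCT counting mistakes. The
per-dataset numbers of any particular real campaign are not reproducible
from synthetic data and are not targets of this package.

## 7. Problem sizes

Default test and reproduction sizes were chosen as the package's own
standard configuration: the full synthetic experiment runs ~840 windows and
~26 000 hits (seconds to analyse end-to-end); estimator-recovery suites use
20 replicates across 10³–10⁵ hits; image tests use 60-slice stacks with
40–80 vessels. All are comfortably within a laptop's budget.

## 8. Known limitations

* The weighted-moment estimator is biased under mixed windows (kept by
  design; see §2) — parameter-recovery guarantees are stated for
  high-contrast/pure windows, and the moment-corrected variant exists for
  recovery studies.
* Registration covers translation + isotropic scale only; rotation and
  elastic deformation reduce detection fidelity and are only guaranteed not
  to make the residual worse than identity.
* The capped ROC construction inflates absolute AUC under heavy mixing
  (§3); use it comparatively.
* Breakpoint estimates are quantized to the strain-quantile grid.
* The smoothing-spline vulnerability values assume a monotone percentage
  curve; heavy non-monotonicity is corrected isotonic-first, which can bias
  levels near flat stretches.
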