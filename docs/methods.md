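# Methods

`spabold` re-implements, as a tested pipeline on synthetic ground truth, an
analysis strategy for sparse-sampling auditory fMRI: how individual
differences in hearing acuity (pure-tone average, PTA) relate to brain
activity during spoken-sentence comprehension. This note documents the
models, the simulator, the numerical choices, and what the validation
studies do and do not establish.

## The acquisition model

The interleaved silent steady-state (ISSS) protocol alternates a silent gap,
during which the auditory stimulus plays, with a burst of volume
acquisitions. Each 14-s trial consists of a 4-s gap (stimulus onset 1 s into
the gap) followed by five volumes at TR = 2 s; a run holds 36 trials
(8.4 min), and an experiment holds four runs. Only volumes inside
acquisition windows exist, so the series is *discontinuous*: 720 volumes per
subject, each timestamped on its run's clock. Because consecutive samples
are separated by trial-length gaps, the usual AR(1) prewhitening is
meaningless and is deliberately absent.

## First level: FIR estimation and the SPA statistic

Each event family (four sentence cells — subject-/object-relative crossed
with early/late adjectival-phrase position — split by response accuracy,
plus one vocoded-noise family) receives five finite-impulse-response (FIR)
indicator regressors, one per post-trial volume. The FIR basis estimates
the response at each acquired lag with no assumption about hemodynamic
shape, which is exactly what a five-sample sparse series calls for. Silence
trials are never modeled: they are the implicit baseline. Nuisance
regressors are six motion series (demeaned per run), one intercept per run
(no global intercept, so the matrix is full rank by construction), and a
per-run discrete-cosine drift basis implementing the 128-s high-pass cutoff,
built from the gapped timestamps (`floor(2·504/128) = 7` columns per run,
each explicitly demeaned because cosines evaluated on a gapped grid are not
exactly zero-mean). Estimation is ordinary least squares per voxel via the
QR factors of the design; rank deficiency is a hard error naming the
collinear columns.

The **summed positive area (SPA)** collapses a condition's five FIR
coefficients into one non-negative number per voxel:
`SPA = Σ_k max(β_k, 0)`. We use the plain sum of non-negative coefficients
(no bin-spacing weight — with a uniform TR any spacing factor is a global
scale) rather than an interpolated integral; the operational definition is
the sum. Composite conditions ("all correct sentences", "errors") are means
of the member conditions' SPA maps, over whichever members were estimable
for that subject. A condition with zero trials is an explicit
condition-absent outcome, never a zero map.

## Second level and cluster inference

Group inference is summary-statistic OLS: voxelwise paired t tests for
condition contrasts and simple linear regressions for subject covariates
(PTA, age, working-memory span, accuracy; all mean-centered, which affects
only the intercept). The residualization scheme regresses the covariate of
interest on nuisance covariates (singly or jointly) and enters the residual
into the voxelwise regression; for a single nuisance variable this
reproduces the partial t of the multiple regression up to the one-df
correction, a tested identity. t maps are converted to Z through log tail
probabilities (`Z = -ndtri_exp(log sf)`), so extreme t values clip at
Z = 38 instead of overflowing.

Cluster-level family-wise-error control follows Gaussian random field
theory: threshold the Z map at the standard-normal quantile of the
voxelwise p (default p < 0.001, positive tail by default with a flag for
decreases), group suprathreshold voxels with 26-connectivity, and assign
each cluster `p = 1 − exp(−E[m]·P(n ≥ k))`, where the expected cluster
count E[m] is the expected Euler characteristic (box-counting resel counts
R₀..R₃ of the search mask times the EC densities, so mask-boundary effects
enter through the lower-dimensional terms) and `P(n ≥ k) = exp(−β k^{2/3})`
with `β = (Γ(5/2)·E[m]/E[N])^{2/3}`. Smoothness is estimated from
variance-normalized residual spatial derivatives:
`FWHM = sqrt(4 ln 2 / λ)` per axis, where λ is the derivative variance of
the unit-variance field — the convention in which a field made by smoothing
white noise with a kernel of FWHM f has smoothness f. Finite differences
under-estimate FWHM by a few percent at ~3-voxel smoothness; calibration is
checked empirically rather than bias-corrected. Cluster volumes are
reported in µl (extent × voxel volume; 27 µl per 3-mm voxel); peaks are
26-connectivity local maxima, at most three per cluster, descending Z with
lexicographic voxel order breaking ties. Clusters with 0.05 ≤ p < 0.1 are
retained with a "marginal" flag rather than dropped.

A permutation oracle (sign-flipping for paired contrasts, covariate
shuffling for regressions; max-cluster-extent null with
`p = (1 + #{null ≥ obs}) / (1 + n_perm)`) validates the analytic path. On
smooth simulated nulls the RFT critical extent runs ~25% larger than the
permutation 95th percentile (slightly conservative), and the realized
family-wise rate sits inside [0.025, 0.075]; at smoothness below ~2.5
voxels RFT degrades and the permutation path should be preferred.

## Behavioral analyses

Trialwise correctness on sentence trials is modeled by a mixed-effects
logistic regression with fixed effects {PTA, age, working memory, syntax,
phrase position, PTA × syntax} and a random per-subject intercept. The
fitter maximizes the exact marginal likelihood with adaptive Gauss–Hermite
quadrature (9 nodes by default; inner Newton iterations locate each
subject's posterior mode, warm-started across evaluations), with Wald
standard errors from the numerically differentiated observed information.
In the τ → 0 limit it agrees with pooled logistic regression to ~1e-5, and
on mixed data with lme4's Laplace fit to well within either method's
approximation error.

The gender judgment is a two-alternative forced choice scored with signal
detection theory, "male" as the signal class: `d' = z(H) − z(FA)`,
`c = −(z(H)+z(FA))/2`, extremes corrected by the 1/(2N) rule. We use the
yes/no formula without the √2 forced-choice divisor, matching the
classification framing of the analysis mirrored here; the divisor is
available behind a flag. Noise-trial button presses (where any press is
acceptable) never enter the SDT computation.

Working-memory span uses weighted scoring: proportions correct at set sizes
1–5, each weighted by its set size, summed and divided by the number of set
sizes, giving a score in [0, 3]. The rule identifier is stored with the
score so an alternative weighting can be swapped without invalidating
stored results.

## The simulator and its defaults

The generator defines the study conditions. Cohorts of 35 subjects draw
PTA from a truncated normal with mean 3.5, SD 5.4 on [−5.0, 23.3] dB HL
(better-ear convention), age mean 25.8, SD 4.6 on [18, 41] years, and span
mean 1.76, SD 0.55 on [0, 3]. Designs satisfy, by construction, the
24 + 6 + 6 per-run composition, six sentences per cell per run, and a
Latin-square rotation assigning each of the 96 (base sentence × variant)
stimuli to exactly one run with one variant per base per run.

Behavior follows the same logistic model the analysis fits. Defaults:
intercept 2.2 (≈ 87% mean accuracy — high but imperfect performance),
PTA slope −0.05 per dB HL (a modest acuity cost), syntax −0.5
(object-relative penalty), phrase position 0 (no effect, matching the
phenomenon emulated), working memory +0.3, age −0.02, PTA × syntax +0.02,
random-intercept SD 0.5. The per-condition accuracy pattern was never
published numerically, so these effect sizes are the package's own
realistic choices, fixed once.

BOLD volumes live on a 20 × 24 × 20 grid of 3-mm voxels (an MNI-like affine
centers the grid at the origin) with an ellipsoidal brain mask (~3200
voxels) and four disjoint spherical effect regions: a left perisylvian
sentence region (+3.0 peak units on sentences), a left anterior syntax
region (sentence response plus +1.5 on object-relative trials), a
right-anterior PTA region (+0.1 per dB HL above the cohort mean, correct
sentence trials only — so below-average hearing yields negative planted
amplitudes there), and a medial error region (+2.0 on incorrect trials).
Responses are double-gamma shaped (peak-normalized; the FIR estimator must
recover this shape without being told it), sampled at the acquired lags
3, 5, 7, 9, 11 s after stimulus onset, with the tail past the 14-s trial
window carried truthfully into later acquisitions of the same run. Noise is
white Gaussian smoothed spatially at the protocol's 9-mm FWHM and rescaled
so the marginal SD equals `noise_sd` exactly (discrete-kernel
normalization); because the data are born smooth, the pipeline applies no
additional analysis smoothing by default (the smoothing operator exists and
is tested separately). A per-run sinusoidal drift (amplitude 1, period
240 s, random phase) falls inside the span of the high-pass basis; an
optional AR(1) switch probes robustness to temporal autocorrelation.
Synthetic motion series are random walks emitted as confounds; they are not
coupled into the data.

The grid size and the study sizes of the validation runs (replicate counts
in `scripts/acceptance.py`) are the package's own choices for desk-scale
experiments; the planted amplitudes were fixed from a signal-to-noise
argument (smoothed noise SD 1, ≥ 20 trials per condition, between-subject
PTA spread 5.4 dB) before the recovery studies were run.

## Numerical and degenerate-case choices

- Smoothing boundaries: analysis smoothing uses zero-padded (constant)
  convolution; simulator noise smoothing uses reflective boundaries.
- Exact fits (zero residual) give ±inf t, clipped through the Z transform;
  0/0 voxels (constant maps) give t = 0.
- Noise-free simulations run in float64 so analytic recovery checks are
  exact; noisy simulations run in float32 for speed.
- Subjects missing a covariate are excluded listwise per analysis; subjects
  with no estimable member condition are absent from that composite group.
- Empty event cells omit their design columns (recorded in the design's
  `omitted_events`), never all-zero columns.
- Seeded determinism everywhere: every stochastic function takes a seed or
  Generator, and per-subject streams spawn from a master `SeedSequence`.

## What passing tests show — and what they do not

The validation studies show that *under the generator's assumptions* the
pipeline recovers what was planted: exact design arithmetic; OLS equal to
an independent pseudoinverse oracle; exact noise-free FIR/SPA recovery
(on schedules whose sentence trial closes the run — with back-to-back
trials the truthful hemodynamic tail biases FIR bins at the few-percent
level, which is treated as approximation error, not corrected); nominal
FWE calibration on smooth Gaussian nulls; ≥ 90% detection of the planted
correct-trial PTA effect at n = 35 with error/noise regressions at the
false-positive floor; and behavioral coefficient recovery with nominal CI
coverage.

They do not establish performance on real data: the simulator omits
physiological and motion-coupled noise, spatial heteroscedasticity,
between-subject anatomical variability and registration error,
non-spherical noise covariance, BOLD nonlinearity, and subject-level
amplitude variability in the planted effects (group-level residual
variance on real data would be larger, and significance claims
correspondingly weaker). Region geometry is idealized spheres on a small
grid, so cluster sizes and peak coordinates have no anatomical meaning
beyond the grid's MNI-like frame.
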