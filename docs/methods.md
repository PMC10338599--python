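# Methods

## Overview

The package implements a remote-monitoring pipeline for COPD symptom episodes:
multichannel personal-exposure streams and daily peak expiratory flow are
windowed into a nonnegative feature tensor, decomposed against a fixed
dictionary of per-(symptom, temporal-state) spectral templates by EM, smoothed
by a Kalman filter over a learned linear dynamic system, thresholded with
ROC-derived cut-offs, and scored with frame-wise F-measures — optionally one
day ahead of the supervised day.

## Preprocessing

**Window geometry.** 8-day windows advanced by 1 day. The window length can be
re-derived from data with `estimate_window_lag`: per participant, the smallest
positive lag at which the peak-flow autocorrelation drops inside the 95%
significance band (±1.96/√N); the cohort window is the rounded median (the
mean is also reported). The significance-band rule is our concretisation; the
autocorrelation criterion behind the original choice of 8 days is not uniquely
determined by anything stronger.

**Features.** Per channel and window, either the plain average
(`average_only`) or a rich set: average, median, variance, maximum, minimum,
kurtosis, skewness, plus spectral flux / centroid / energy / entropy computed
on the band energies of a multilevel Daubechies DWT (db2, 3 levels by default,
periodization mode so the transform is orthogonal and invertible). Band
energies are computed on the mean-removed window: spectral features describe
fluctuation across scales, the level is already carried by the location
features. Flux compares square-root band energies against the previous frame
of the same channel and resets across coverage gaps. Constant windows define
skewness, kurtosis and flux as 0.

**Nonnegativity: rectified on/off deviation coding.** The decomposition needs
a nonnegative tensor, and the channels mix incommensurable units. Each raw
feature row is standardised against its training-split median/standard
deviation and split into a rectified positive-deviation row and a rectified
negative-deviation row. Two reasons drive this choice over a simple
shift-to-zero: (i) a shared additive baseline would dominate every template,
leaving near-collinear templates whose EM attribution is decided by
initialisation noise rather than data; (ii) an energy-based decomposition can
only key on the *presence* of mass, so a biomarker that expresses itself by
dropping — peak flow during an episode — would be invisible without the
off-row that converts the deficit into positive energy. The statistics are
fitted on training frames only; test frames are transformed with the same
parameters.

**Missingness.** Missing samples are dropped within a window, never imputed. A
channel is valid in a frame when ≥50% of its expected samples are present; a
frame with no valid channel is dropped (its date recorded). Sensor subsets:
`all` (every channel plus daily peak flow as an extra channel),
`pollutants_only` ({NO, CO, PM1, PM2.5, PM10, RH}), `peakflow_only`.

**Labels.** Daily diary indicators per symptom class, plus the
worsening-of-peak-flow biomarker: 1 strictly below the personal median, 0 at
or above (equality is not worsening), missing days stay missing. When a
peak-flow series exists, the derived biomarker *replaces* a diary class named
`lung_capacity` — lung capacity is measured, not self-reported, and keeping
both would duplicate one episode process as two competing label classes, which
a sum-to-one mixture cannot both detect. Episodes are maximal runs of ones:
onset = first day, offset = last day, transients strictly interior; a
single-day episode counts as both onset and offset.

## Dictionary

For every (s, a) cell — further split by season for the 4D model — the
labelled training frames are factorised by KL-divergence NMF (multiplicative
updates, 500 iterations or relative improvement < 1e−6, seeded) and the
rank-1 basis column, normalised over features, becomes the template. Rank > 1
stacks extra components as pseudo temporal states (off by default: the
dictionary is indexed exactly by (f, s, a)). Empty cells are imputed with the
mean template of their symptom (4D: first across seasons within the cell),
falling back to the global mean; imputations are logged. Templates are fixed
after the build.

**Background template.** By default the pipeline appends one pseudo-symptom
whose cells are built from symptom-free training frames. Without it, healthy
frames must be explained by some real class, and the class with the most
widespread episodes becomes the "default winner", inverting its scores
(empirically: anticorrelated with its own truth). The background row is
excluded from scoring and evaluation. This mirrors standard practice in the
template-based sound-event-detection literature this method family comes from.

## Decomposition

E-steps compute the posterior over latent (s, a) — or (m, s, a) — per
(feature, frame); M-steps re-estimate `P(s|t)`, `P(a|s,t)` (and `P(m|s,t)`)
from posterior-weighted data. The sparsity exponent κ (default 1.1) is applied
to the unnormalised symptom masses before renormalisation; κ = 1 is exact EM
and provably non-increasing in the energy-weighted KL divergence
`Σ_t P(t)·KL(V̄_t ‖ Q_t)`, which is recorded per iteration. With κ > 1
monotonicity is not guaranteed (not asserted anywhere). Zero-denominator
posterior columns fall back to a uniform posterior (logged) so silent frames
cannot propagate NaNs. Fitting runs a fixed 40 iterations by default, with an
optional early stop at relative KL change < 1e−7.

**Initialisation.** `fit_plca` defaults to uniform random values in (0, 1),
normalised, as the method was originally described. The *pipeline* passes
`init="uniform"` (every distribution flat — the mean of the random-init
distribution): with realistic, highly collinear templates the random draw
otherwise decides the symptom attribution more than the data does, and the
deterministic init makes end-to-end runs reproducible without a seed sweep.
Explicit initialisers override both; a ground-truth binary mask keeps its
zeros under the multiplicative updates, which is how "clean" training
activations for the LDS are produced. Frames with no active symptom normalise
to a uniform init column; with the background class enabled the background row
claims them instead.

## LDS tracking

States stack per-symptom activation levels over their first differences
("velocities"); the first frame's velocity is 0. `A` and `H` are least-squares
solutions of `z_{t−1} → z_t` and `z_t → y_t` via normal equations with ridge
1e−8 (rank safety); training pairs never straddle sequence boundaries.
`Q = αI`, `R = βI` with defaults α = 0.2, β = 0.1; `z0 = 0`, `Σ0 = I` (the
original description leaves initial conditions unstated). The filter is the
standard product-form recursion — the printed gain equation in the source
material contains a typographical "+" where the product belongs; the sum is
dimensionally inconsistent and the hand-workable numbers match the product
form. Observation prediction uses the one-step-ahead state. Missing
observation frames take a prediction-only step (zero gain). Covariances are
symmetrised each step; an eigenvalue below −1e−8 raises a numerical error.
Tracked output is the first S rows of the posterior mean, clipped at 0.

The LDS is trained per participant by default (shared across the cohort in
the population regime); whether the original system shared one tracker is not
determinable, and both are exposed.

## Thresholding and evaluation

Candidate cut-offs are midpoints between consecutive distinct scores plus
sentinels one unit outside the observed range. Each candidate is scored by
`TPR + (1 − FPR)` under the decision rule `score > θ`; the final cut-off
averages up to five candidates that *attain* the maximum (preferring higher
thresholds when more tie) — averaging literal "top 5" candidates regardless
of ties would pull the cut-off away from a perfectly separating threshold.
Single-class training labels give θ = +∞ (never fire, with a warning).
Thresholds are fitted strictly on training frames. Evaluation is frame-wise
precision/recall/F1 per (symptom, target) with target ∈ {overall, onset,
transient, offset}; undefined ratios are 0. Personalised grouping averages
per-participant F1; population grouping pools frames first. No event-level
tolerance windows are applied (none are defined for the method).

## Experiment orchestration

Per participant: labels and masks → feature tensor → one-day-ahead alignment
(the frame ending at day t is supervised by day t + horizon; trailing frames
are dropped) → half-month split (calendar days 1–15 of each month train, the
rest test, applied to the supervised day) → dictionary from training frames →
EM on both splits → optionally LDS learned from masked-init training
activations (observations: the plain training activations) and applied to
both splits → thresholds on training scores → F1 on test frames. Per-state
decision scores multiply the (tracked) symptom activation by `P(a|s,t)`.

The personalised regime keeps a symptom only if each temporal state occurs at
least once among training *and* test frames — the retention filter inspects
test-phase label structure by design, so the retained label set (not the
trained artifacts) depends on test days. The population regime keeps any
symptom that occurs anywhere, builds one shared dictionary and one shared
tracker, and pools frames for thresholds and evaluation. Coverage filtering
(e.g. the 60% rule) drops participants below the threshold before anything
else.

A label-shuffle null is provided for calibration: per (participant, symptom),
the mean F1 over N random permutations of the test-frame truth with decisions
held fixed; the win fraction is reported per symptom class (mean F1 across
participants against the matching mean null) or per pair.

## Synthetic cohort

What it emulates: per-participant whole-day contiguous coverage gaps hitting a
configured coverage fraction (participants leave the device at home; within-day
gaps are not modelled); log-normal AR(1) pollutant channels sharing a daily
pollution factor (positive, right-skewed, autocorrelated, co-varying);
Gaussian meteorology/noise/activity channels; episodic multi-label diaries
whose per-day start hazard rises with the z-scored pollutant average over the
lagged window (`logit p_t = logit p_0 + coupling_strength · z̄`), episode
length 1 + Poisson(transient_mean_days + 1); daily peak flow = personal
baseline (≈ N(350, 40) L/min) + slow AR(1) physiological drift (sd 15, φ 0.9)
+ measurement noise (sd 4), depressed by 15% of baseline during lung-capacity
episodes — the drift matters: with iid-only noise the median-split biomarker
would label near-random borderline days, which no real lung produces. Season
labels follow 91-day blocks starting at spring.

Defaults: 10 participants, 120 days, 24 samples/day, coverage spread evenly
over [0.55, 1], episode_rate 2/month, transient_mean_days 3, coupling lag
1 day, coupling_strength 1. Episode onset counts implied by the original
cohort peak near 1.7/month for the most frequent class, so rates of 1–2/month
are the realistic band.

What it does not emulate: device drift/calibration, indoor/outdoor
microenvironments, GPS trajectories, within-day missingness, diary
non-compliance, inter-symptom causal structure beyond the shared pollution
driver. Passing tests therefore demonstrate correctness of the machinery and
detectability under the stated couplings — not clinical performance on real
cohorts.

`sample_from_plca_model` draws exact (expectation-mode) or multinomial frames
from the mixture itself and exists for parameter-recovery validation.

## Numerical choices

KL computations floor the reconstruction at 1e−300 inside the log only;
0·log 0 = 0. Conditional distributions renormalise after every M-step
(tolerance 1e−9 asserted). All-zero mass columns become uniform. NMF,
EM and cohort generation take explicit seeds; per-participant streams derive
from crc32 of the participant id so runs are reproducible across processes.
Experiment problem sizes used in validation (10 × 120 days, 24 samples/day)
keep a full run in tens of seconds on one core.

## Known limitations

- The sum-to-one symptom activation makes concurrent symptoms compete;
  heavily overlapping classes depress each other's scores even with the
  background template present.
- Single-day temporal states (onset/offset) are intrinsically hard at 8-day
  window resolution; their F1 sits far below whole-episode detection, on
  synthetic and (reportedly) real data alike.
- The seasonal 4D model needs multiple seasons of labelled data per cell;
  with ≤182-day records most season cells are imputed, and the model rarely
  beats its 3D counterpart.
- Frame-wise F1 treats every frame independently; no credit or collar is
  given for near-miss boundary placement.
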