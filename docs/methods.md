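# Methods

`gliasleep` re-implements, as a tested library, the signal-analysis stack
used to study how microglia Gi/Ca²⁺ signaling interacts with sleep and
norepinephrine (NE) transmission: EEG/EMG sleep scoring, two-photon
calcium-trace event detection, brain-state-aligned trace summaries,
GRAB-sensor pharmacology contrasts, and 3D bouton-to-microglia distance
analysis.  Because no in-vivo recordings ship with the package, every stage
is validated against seeded synthetic data whose hidden structure is known
exactly.  This note documents the models, the defaults and why, the
numerical choices, and what the synthetic validation does and does not
establish.

## Sleep scoring

**Model.** Brain state is scored per non-overlapping 5-s epoch from two
channels sampled at 1500 Hz.  For each epoch the EEG power spectral density
is computed by FFT periodogram (7500-sample epochs give 0.2-Hz resolution);
band powers are trapezoidal integrals with the band edges interpolated onto
the frequency grid: delta 0.5–4 Hz, theta 6–9 Hz, and a 0–25 Hz total used
to normalize state-conditioned spectra to unit area.  The EMG is band-passed
(10–300 Hz, 4th-order zero-phase Butterworth; the upper edge is clipped to
0.45·fs for low sampling rates) and summarized as per-epoch RMS.

**Decision rule.**  Per epoch: (1) EMG RMS above threshold → wake;
else (2) theta/delta ratio above 1.5 → REM; else NREM.  The EMG threshold
defaults to the midpoint of a two-class 1-D k-means clustering of the
session's log EMG RMS, so it adapts to gain; it can be fixed explicitly.
An optional smoothing pass relabels isolated single epochs flanked by two
identical states; with smoothing off the rule is a pure per-epoch map.
Wake is decided on EMG alone — "desynchronized EEG" is not used as a
separate feature, because muscle tone is the operative wake discriminator
and using it avoids a third free threshold.  A manual-override CSV
(epoch index → state) can replace the label of any epoch, standing in for
manual curation of a semi-automatic scorer.  Epochs are half-open
[start, start + 5 s) with 0-based indices; a trailing partial epoch is
dropped.

Consecutive identical epochs merge into episodes (maximal runs).  Metrics:
per-bin time-in-state percentages (rows always sum to 100; a trailing
shorter bin is normalized to the epochs it contains), mean episode duration
per state over the analysis window (reported missing — NaN — when the state
never occurs, not zero), and episodes per hour.

## Calcium analysis

**Baseline and ΔF/F.**  F0 is the 0.25 quantile
(linear-interpolation definition) of the raw fluorescence in a ±600-s
sliding window, truncated (not reflected) at the trace edges;
ΔF/F = (F − F0)/F0.  The rolling quantile is validated exactly against
per-frame brute-force recomputation.

**Event detection.**  The threshold is mean + 3 s.d. of the *entire* ΔF/F
trace.  A transient is a maximal run of at least three consecutive frames
strictly above threshold; runs separated by one or more subthreshold frames
are distinct events.  Onset = first frame of the run, peak = argmax within
the run, amplitude = peak ΔF/F (not peak minus threshold), duration =
run length / frame rate.  A moving-average variant (smooth the trace over
k frames before thresholding) is available behind `smooth_frames` for the
alternative reading of the three-frame rule.  Detection is invariant to
offsetting or rescaling the raw fluorescence, since ΔF/F absorbs affine
gain.  Event statistics per window: mean z level, mean amplitude of events
whose *peak* falls in the window (missing when none), events per minute.
z-scores are computed against a designated baseline period (mean and
n−1 SD), 40 min before systemic injections and 20 min before local drug
application.

**Known behaviour of the threshold rule.**  Because the threshold is
estimated from the whole trace, the events themselves inflate the SD and
raise the threshold; with slow decays this also fragments the suprathreshold
tail into spurious extra runs.  Quantitatively, at 0.84 Hz the third
consecutive frame of a transient with peak exactly 5× the frame noise sits
within ~1 noise SD of the inflated threshold, so such events cannot be
recovered with both precision and recall above 0.9 — this is a property of
the detection rule, not of any implementation.  The standard synthetic
benchmark therefore plants amplitudes with a *floor* of five times the
ΔF/F noise SD (normal with mean 0.8 and SD 0.08 ΔF/F on ≈0.107 noise), at
0.1 events/min and a 10-s decay — sparse, well-resolved transients of the
kind the rule is designed for.

## Transition alignment

Frames map to epochs by floor(time/epoch length) under the half-open
convention.  State means exclude REM by default (imaging during REM is
confounded by hemodynamic changes).  A transition is a boundary where a
≥30-s episode of the source state is immediately followed by a ≥30-s
episode of the target state; both the flank criterion and the ±60-s
peri-transition window are free parameters with no canonical value, chosen
to span a few epochs on either side while keeping flanking states pure.
Segments are stacked on the trace's own frame grid (nearest frame);
transitions whose window leaves the trace are dropped with a log entry.
The contrast is mean(post) − mean(pre) of the aligned average; its SEM is
undefined (NaN) with a single usable transition.

## Sensor contrasts

Each GRAB_NE / GRAB_ADO session carries 8–12 ROI traces at 1.68 Hz.  Every
ROI is z-scored against its own baseline period; ROIs with zero baseline
variance are dropped with a warning.  The session trace is the unweighted
mean of ROI z-scores (per-session dots in the source analyses are session
averages; no ROI weighting is specified anywhere, and the unweighted mean
is the simplest choice).  Two contrasts are exposed:

- **Local drug:** Δz = mean z in [40, 60] min minus mean z in [−20, 0] min
  relative to application.
- **Systemic injection:** Δz = mean z in [20, 120] min minus the mean over
  the session's own z-scoring baseline (the 40-min pre-injection period).

The step estimator is exactly unbiased for an instantaneous step and its
bias grows with the effect's onset time constant relative to the
post-window start; with a 600-s default onset (effects developing over tens
of minutes) and the [40, 60]-min window the residual bias is below 2% of
the step size.

## Bouton-to-microglia distances

The microglia segmentation is a binary (z, y, x) voxel mask with physical
sampling 1 × 0.41 × 0.41 µm by default; boutons are (x, y, z) points in µm
with the origin at the centre of voxel (0, 0, 0).  Distances come from an
exact Euclidean distance transform of the background with per-axis sampling
equal to the voxel size, evaluated at each bouton's containing voxel;
boutons inside the mask get 0.  Distance is therefore measured to the
nearest foreground *voxel centre*, not a subvoxel surface — a convention
choice.  Against analytic sphere ground truth the quantization error is
typically within one voxel diagonal (≈1.16 µm at default sampling; the
geometric worst case is 1.5 diagonals, from half a diagonal of bouton
discretization plus up to one diagonal between the nearest surface point
and the nearest inside-voxel centre), and
against brute-force enumeration of foreground voxel centres the EDT is
exact to 1e-6 µm.  Boutons are treated as points; their physical extent is
ignored.

## Group statistics

Two-sample comparisons are gated on a normality test of the paired
differences (Shapiro–Wilk up to n = 50, D'Agostino–Pearson above — the
cutoff is a convention): normal → paired/unpaired t-test, otherwise
Wilcoxon signed-rank / Mann–Whitney U, all two-sided.  The degenerate
all-equal paired case reports p = 1.  Null simulations (20,000 reps,
n = 10 pairs) put the empirical type-I error of the full gated procedure at
≈0.05.  Treatment × time designs use repeated-measures two-way ANOVA
(statsmodels AnovaRM; balance is checked and missing cells are reported)
with per-time paired contrasts adjusted by Bonferroni
(p_adj = min(1, m·p)) or Holm–Šídák; one-way designs use ANOVA with
Holm–Šídák pairwise contrasts.  Sphericity corrections are not applied by
default.

## Synthetic data: what it emulates, and what it does not

- **Sleep sessions.**  Hidden states follow a first-order Markov chain at
  epoch resolution (default dwell times ≈2.8 min wake, ≈2.4 min NREM,
  ≈0.8 min REM; REM entered only from NREM, exited to wake).  The EEG is a
  sum of band-limited Gaussian noise components (delta, theta, 0.5–25 Hz
  broadband) whose per-epoch variance follows the state's configured band
  power (defaults: NREM delta and REM theta 5× wake); EMG is white noise
  with 5× RMS in wake.  Real EEG has 1/f structure, spindles, artifacts and
  gradual state transitions; none are modelled, so scoring accuracy on this
  generator (>99%) is an upper bound demonstrating correctness of the
  pipeline, not expected field performance.
- **Calcium traces.**  Baseline + slow sinusoidal drift + instant-rise /
  exponential-decay transients at Poisson onsets + white Gaussian noise.
  Transient amplitude is defined as peak ΔF/F relative to the local
  drifting baseline, making the planted peak analytic.  Real microglia
  transients have finite rise times and correlated noise.
- **Sensor sessions.**  Constant baseline + saturating-exponential drug
  step (size in units of the frame noise SD, so the injected size is the
  ground-truth Δz) + optional per-state offsets driven by a hypnogram +
  white noise.
- **Volumes.**  Unions of rasterized spheres on the anisotropic grid with
  uniformly scattered boutons; minimal distances to the sphere surfaces are
  analytic, giving exact ground truth up to the documented voxel
  quantization.

Every generator is a pure function of its configuration including the
seed; all randomness flows from one `numpy` Generator per call.

## Problem sizes used in the bundled validation

The test-suite and `scripts/acceptance.py` run at the following sizes,
chosen to give tight Monte-Carlo intervals while completing quickly on one
CPU: ten 3-h sleep sessions (21,600 epochs); 100 random traces for the
baseline oracle; the five-set detection benchmark (50 ROIs × 40 min);
100 × 1000-frame null traces; 20 seeds per sensor effect level and per
state-coupling pattern; 50 random distance scenes (≤64³ voxels) plus the
default 20-sphere/500-bouton scene; 20,000 null replicates for test
calibration.
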