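# Methods

`thetalink` implements the oscillatory-analysis chain of a retro-cue EEG
design contrasting two task demands on identical stimulus–response (S-R)
mappings: *implementation* (prepare to execute the instructed response) vs
*memorization* (maintain the mapping declaratively). Analyses operate on
epoched, source/ROI-level data — trials × sources × time — time-locked to
the retro-cue (−1.0 to 2.5 s, 512 samples/s by convention), with a
per-trial table of task, cued side, response side, correctness, catch flag
and RT.

## Band power and ROI time courses

Power is computed with complex Morlet wavelets at integer-Hz steps — theta
3–7 Hz at 3 cycles, alpha 8–14 Hz at 4 cycles, beta 15–30 Hz at 5 cycles —
averaged across each band's frequencies and decimated to a 128 samples/s
power grid. Decimation happens *after* band averaging, through a zero-phase
FIR anti-alias guard (`scipy.signal.decimate`); on band-limited power
traces this matches decimate-then-average within numerical tolerance, and
the order is fixed so the convention is reproducible. No baseline
normalization is applied: every contrast is within subject between
conditions of raw induced power, so a common scale cancels.

ROI summary time courses use the `pca_flip` rule: member sources are
orientation-sign adjusted, the first right singular vector of the
source × time matrix is taken per trial, rescaled so its RMS equals the
mean RMS of member sources, and sign-aligned with the sign-adjusted ROI
mean. Rank-0 (all-zero) trials return a zero trace with a warning.

Edge handling: the epoch exceeds the 0–1.8 s analysis window by at least
one wavelet half-length on both sides (the longest wavelet is 1 s, theta at
3 cycles / 3 Hz); `check_edge_margin` refuses configurations that would let
filter or wavelet transients leak into the window.

All time windows are closed intervals (inclusive endpoints); time is in
seconds relative to the retro-cue, sample 0 at `tmin`. On the 128 Hz grid
starting at −1.0 s, the per-trial theta window 0.355–0.985 s contains 81
samples; at 512 samples/s (connectivity) it contains 323 samples.

## Laterality contrasts and cluster statistics

Left/right ROI power is reordered per trial into contralateral/ipsilateral
relative to the cued side (alpha, lateral-occipital ROIs) or the response
side (beta, hand-area ROIs). Subject × condition mean time courses enter
pointwise paired t statistics; 2 × 2 within-subject designs (Task ×
Laterality) use F = t² on the per-subject effect contrast — main effects
are averaged simple differences, the interaction the double difference
(A1−A2)−(B1−B2), which is exchangeable under the no-interaction null.

Clusters are maximal runs of contiguous suprathreshold samples with a
common sign, thresholded at the pointwise α = 0.05 critical value; cluster
mass is the sum of the statistic over the run (F units for F tests). The
null is max-cluster mass over sign-flip permutations of the per-subject
contrasts (default 10,000). The p-value is the fraction of permutation
maxima ≥ the observed mass; ties count against the observed, the
denominator is the permutation count, so the smallest reportable p is
1/n_permutations. One-sided contrasts (the directional beta
Task × Laterality interaction; theta Implementation > Memorization) use the
one-sided critical value and signed masses. Effect size per cluster is
Cohen's d of the window-averaged per-subject differences (n−1 SD
everywhere in the package). Every reported cluster carries the caveat that
its boundaries inherit only cluster-level inference.

Zero-variance timepoints get statistic 0 (cannot cross threshold) with a
warning; degenerate zero-spread effect sizes are flagged NaN/infinite.

## Connectivity

Theta phase comes from filter–Hilbert, not wavelets: a Hamming-window FIR
bandpass 3–7 Hz (0.0194 passband ripple, 53 dB stopband, 2 Hz transitions;
cutoffs half a transition band outside the passband; length 3.3/width,
forced odd and applied as a zero-phase symmetric kernel), then the analytic
signal. Within-trial PLV over the 355–985 ms window is
|mean_t exp(i(φ₁−φ₂))|; region pairs use the multivariate rule: the RMS of
the M × N matrix of pairwise source PLVs. wPLI is |Σ Im X| / Σ |Im X| with
X the cross-spectrum sample; a pure zero-lag relation returns 0 with a
degeneracy flag. wPLI aggregates across source pairs with the same RMS rule
(a package decision; the pairwise definition does not dictate one).
Connectivity uses only correct regular (non-catch) trials and the raw
sampling rate, never the decimated power grid. The mPFC seed is paired with
Hand and LatOcc targets (laterality from response side and cued side
respectively) and with a parahippocampal control pair fitted with a
Task-only model.

## Mixed models and mediation

Trial-level models are REML linear mixed models with fixed structures fixed
a priori (no selection): RT ~ Task, θ ~ Task, RT ~ θ + Task, and
PLV ~ Task × Laterality, each with a random intercept and Task slope per
subject (`(1 + Task | Subject)` in lmer notation). Fitting goes through
statsmodels MixedLM; singular random-effect fits fall back to
intercept-only and are flagged. p-values use the normal approximation on
the Wald statistic — Satterthwaite degrees of freedom are not available in
this stack, and the package's inferential behavior is instead calibrated by
simulation (type-I and recovery checks in the test suite).

Before modelling, per-trial theta scalars (mean theta power in
0.355–0.985 s) are trimmed at 3 SD around the subject's mean across tasks,
and RTs at 3 SD separately per subject and task; trimming is a single pass
(mean/SD from the full input, never iterated).

Mediation of the task effect on RT via theta follows the classic criterion
chain (task→RT, task→θ, θ→RT given task), then estimates ACME = a·b,
ADE and the total effect. Uncertainty comes from a nonparametric bootstrap
resampling subjects with replacement (default B = 1,000; percentile 95%
CIs; p = 2·min(frac ≤ 0, frac ≥ 0), floored at 2/B). This replaces the
quasi-Bayesian machinery some toolboxes use: the estimands are the same and
the procedure is fully specified here. The bootstrap inner loop uses an
in-package profiled-REML fitter for the random-intercept + slope family:
per-subject sufficient statistics (X'X, X'y, Z'X, Z'Z, Z'y, y'y, n) make a
resampled refit a 3-parameter optimization over 2 × 2 matrices, and all B
draws advance through a vectorized Nelder–Mead in lockstep. Its estimates
match statsmodels MixedLM to ~4 significant digits (asserted in tests);
statsmodels remains the reporting path for the criterion-chain models.

Behavioral group tests compute per-subject means first, then compare tasks
with a paired t test unless Shapiro–Wilk on the paired differences rejects
normality (p < 0.05), in which case a Wilcoxon signed-rank test is used
(exact null below 5 subjects); RT and error rate are tested separately for
regular and catch trials.

## Subject and trial filtering

A subject is excluded when overall regular-trial accuracy falls more than
2.5 SD *below* the group mean — the deviation rule is read as low
performance — or when catch-trial accuracy falls below 60% in either task,
with machine-readable reasons. Power analyses use correct trials including
catch trials; connectivity and mediation use correct regular trials only.
The pipeline asserts trial-accounting conservation per stage
(n_input = n_analyzed + n_excluded).

## Synthetic data generator

The generator produces group datasets with exactly the structure the
analysis assumes, so every stage can be tested against known ground truth.
Each ROI carries one composite oscillatory signal per trial; member sources
observe it through per-source gains (uniform 0.75–1.25, drawn per subject)
on top of independent 1/f background noise (spectrally shaped white noise,
exponent 1), so within-parcel coherence is high — as in source-leaky real
data — and the SVD summary recovers the composite. Oscillation amplitude is
`snr` (default 3) times the unit background SD; a per-subject, per-band
amplitude multiplier (SD 0.15) provides between-subject variability, and
per-trial amplitude jitter (SD 0.25, every band) provides the
trial-to-trial power fluctuation real induced activity shows — without it,
subject-level task differences have an unrealistically tiny noise floor and
any ppm-level systematic leak becomes "significant".

Condition structure:

* LatOcc alpha amplitude ×(1 − 0.30) contralateral to the cued side;
* Hand beta amplitude ×(1 − 0.25) contralateral to the response side,
  optionally scaled further in implementation (default off, mirroring the
  marginal interaction the design anticipates);
* mPFC theta amplitude ×(1 + 0.30) in implementation, with trial-level
  amplitude jitter (SD 0.25);
* posterior theta (0.7 × snr) whose phase is the mPFC wandering theta
  phase plus a π/4 lag plus band-limited Gaussian-autocorrelation jitter
  (SD 0.2 s temporal scale) of circular SD 1/√κ, with κ = 8
  (implementation) vs 2 (memorization); the
  parahippocampal control pair gets an independent phase; κ = 0 means no
  shared process at all. A zero-lag mode exists to demonstrate that wPLI
  (unlike PLV) is blind to zero-lag coupling.
* RT for regular trials: 830 ms + 500 ms·[memorization] − 40 ms·θ_true +
  subject intercept (SD 100 ms) + subject task slope (SD 50 ms) + residual
  (SD 150 ms), where θ_true is the trial's true mPFC theta amplitude in the
  355–985 ms window — the mediation ground truth. Catch RTs are 110 ms
  slower with a quarter-size task effect. Accuracies: 0.940/0.911 regular,
  0.965/0.964 catch; 10% catch trials; 1% no-response trials (missing RT).

All condition effects ramp on over 200–300 ms post-cue (raised cosine) and
are sustained, so they are fully established inside every analysis window.
Trials are balanced over the 2 × 2 cued × response cells within each task
(cells differ by at most one trial). Per-subject seeds derive
deterministically from the group seed via `SeedSequence`; behavior and
signals use separate child streams, so `signals=False` reproduces the
behavioral table bit-exactly without synthesizing signals.

Two generator choices deserve emphasis because earlier drafts got them
wrong in instructive ways. First, phase-coupling jitter must be
band-limited: an AR(1) jitter has a white derivative whose FM sidebands
leak task-dependent (κ-dependent) energy into the alpha and beta bands,
manufacturing spurious task effects in contrasts that should be null; the
Gaussian-autocorrelation jitter (SD 0.2 s) keeps sidebands inside the
theta band. Second, coupling is generated by a shared phase process rather
than additive signal mixing, so target PLV is controllable independently of
power — the same dissociation the study design relies on.

What the generator does not emulate: volume conduction between ROIs (beyond
the within-ROI mixing), eye/muscle artifacts, non-stationary drift across
blocks, evoked (phase-locked) components, and any forward-model geometry.
Passing tests therefore demonstrate correctness of the estimators and the
inferential calibration under the assumed structure, not robustness to
those real-data complications.

## Problem sizes and numerical choices

Test and acceptance runs scale the simulation down while keeping the
paper-mirroring structure: end-to-end checks use 16 subjects × 96
trials/task at 256 samples/s with 1,000 permutations and B = 300; mediation
recovery uses 30 subjects × 100 trials/task (behavior-only fast path) with
B = 500 over 100 simulated groups. Generator defaults remain at the study
conditions (30 subjects, 240 trials/task, 512 samples/s). The calibration
checks pin the familywise false-positive fraction of the cluster test to
[0.03, 0.07] under exchangeable nulls and ≥ 90% detection of a d ≈ 1,
300 ms difference at 20 subjects.

Known limitations: normal-approximation LMM p-values are mildly liberal at
small subject counts (hence the simulation calibration); the percentile
bootstrap CI for ACME covers at ~93–95% rather than exactly 95% at 30
subjects; the wPLI estimator is the standard non-debiased form; cluster
boundary timing is not pointwise inference; and the end-to-end qualitative
pattern includes two null checks at α = 0.05 per run, so occasional single
runs will fail one of them by construction.
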