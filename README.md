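# thetalink

Theta-band EEG analysis of how the brain prepares to *implement* novel
stimulus–response instructions, as opposed to merely *maintaining* them.

In retro-cue designs contrasting these two task demands, three oscillatory
signatures and one network effect are expected during the cue–target
interval:

* **alpha (8–14 Hz)** power suppressed in lateral-occipital cortex
  contralateral to the cued hemifield — attentional prioritization, equal
  across tasks;
* **beta (15–30 Hz)** power suppressed over the motor hand area
  contralateral to the instructed response hand — motor preparation;
* **theta (3–7 Hz)** power in medial prefrontal cortex (mPFC) larger when
  the instruction must be implemented — and mediating, trial by trial, the
  effect of task demands on reaction times;
* **theta-phase connectivity** between mPFC and motor/visual regions
  stronger under implementation demands, absent for a control region pair.

`thetalink` implements the full analysis chain for epoched ROI-level data,
plus a synthetic-data generator that produces group datasets with exactly
this statistical structure, so the whole pipeline runs and is testable with
no external download.

## What is inside

| stage | statistic / algorithm |
| --- | --- |
| `thetalink.dataio` | containers (HDF5 epochs + JSON sidecar, BIDS-events-like `trials.tsv`, `rois.json`), 3 SD single-pass trimming, 2.5 SD / 60%-catch subject exclusion |
| `thetalink.synthetic` | 1/f background + band oscillations with condition-dependent amplitudes, von Mises-style theta phase coupling (concentration κ per task, lag π/4), RTs with a built-in mediation structure |
| `thetalink.spectral` | Hamming FIR filter–Hilbert phase, Morlet band power (θ/α/β at 3/4/5 cycles, 1 Hz steps, 128 Hz power grid), `pca_flip` ROI summaries, contra/ipsilateral reordering |
| `thetalink.connectivity` | within-trial PLV, multivariate PLV = RMS of the M×N pairwise matrix, wPLI (zero-lag-blind control) |
| `thetalink.cluster_stats` | pointwise paired t / 2×2 repeated-measures F, cluster mass = Σ statistic over suprathreshold runs, sign-flip max-cluster permutation null, Cohen's d per cluster |
| `thetalink.inference` | REML mixed models (`RT ~ θ + Task + (1 + Task | Subject)` etc.), Baron–Kenny chain, ACME/ADE via subject-level bootstrap |
| `thetalink.pipeline` | `run_all` orchestration, trial accounting, JSON + text report |

The key estimator, for two regions with sources M and N and theta phases
φ extracted by filter–Hilbert, is the per-trial multivariate phase-locking
value over the 355–985 ms window:

    PLV(m, n) = | (1/T) Σ_t exp(i (φ_m(t) − φ_n(t))) |
    PLV(ROI1, ROI2) = sqrt( (1/MN) Σ_{m,n} PLV(m, n)² )

and cluster inference compares each observed cluster mass with the maximum
cluster mass of 10,000 sign-flipped permutations.

## Worked example

```python
import thetalink as tl

sim = tl.SimConfig(n_subjects=16, n_trials_per_task=96, srate=256.0, seed=100)
ana = tl.AnalysisConfig(n_permutations=1000, mediation_B=300, rng_seed=100)
report = tl.run_all(sim_config=sim, analysis=ana)
print(report.summary())
```

prints (exact output of this configuration):

```
thetalink run report (v0.1.0)
subjects analyzed: 16 (excluded: none)

RT regular: 674 vs 1240 ms (paired_t, stat=-44.95, p=2.06e-17)
alpha_laterality/task: no significant cluster
alpha_laterality/laterality: significant cluster 0.172-1.797 s, p=0.001, d=-4.46
alpha_laterality/interaction: no significant cluster
beta_laterality/task: no significant cluster
beta_laterality/laterality: significant cluster 0.203-1.797 s, p=0.001, d=-2.89
beta_laterality/interaction: no significant cluster
beta_laterality/interaction_one_sided: no significant cluster
theta_task: significant cluster 0.148-1.797 s, p=0.001, d=3.35
mediation: ACME=33.7 CI95=[29.179231381491917, 38.17339700042984] p=0.00667; ADE=530 p=0.00667
plv mPFC-Hand: task beta=-0.06118 p=6.7e-141
plv mPFC-LatOcc: task beta=-0.06288 p=1.15e-37
plv mPFC-Control: task beta=-0.008852 p=0.2
wpli mPFC-Hand: task beta=-0.1019 p=1.1e-52
wpli mPFC-LatOcc: task beta=-0.1021 p=1.27e-53
wpli mPFC-Control: task beta=-0.007778 p=0.351

Cluster boundaries reflect cluster-level inference only; the first and last
time points of a cluster are not individually significant and must be
interpreted cautiously.
```

Reading the output: implementation is ~565 ms faster than memorization;
alpha power shows a contralateral-suppression cluster (Laterality main
effect, d = −4.46 on this synthetic group) with no Task effect; beta shows
the response-hand laterality cluster; mPFC theta is larger during
implementation (one-sided cluster, d = 3.35) and partially mediates the
task effect on RT (ACME ≈ 34 ms of the ≈ 564 ms total). Task modulates
theta-phase PLV for both mPFC–Hand and mPFC–LatOcc (negative β: the model
codes memorization = 1, so implementation has the higher PLV) but not for
the parahippocampal control pair, and wPLI confirms the pattern at the
built-in π/4 coupling lag.

The same run from a shell:

```bash
thetalink run-all --seed 100 --n-perm 1000 --out results/
thetalink simulate --seed 1 --out data/           # write a dataset to disk
thetalink connect --data data/ --out conn.tsv     # trial-level PLV/wPLI table
```

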