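# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data experiments do and do not
demonstrate.

## Session structure

A session is one decoder-training run followed by three regulation runs,
each with 24 attention blocks (12 interoceptive alternating with 12
exteroceptive; the starting condition is configurable and inert by
symmetry, default interoceptive).

* Decoder-training trial: 12-s rest, 10-s attention; the run closes with a
  final rest period so that the haemodynamically shifted feature window of
  the last trial stays inside the acquisition (270 volumes at TR 2 s).
* Regulation block: 10-s rest, 10-s regulation, 6-s rating, 4-s feedback,
  after an opening 20-s fixation baseline (370 volumes).

Volume indices are 0-based and post-dummy (3 dummy volumes, TR 2 s).
Feature windows are the last five attention-period volumes shifted forward
by `hemodynamic_shift` volumes (default 2 ≈ 4 s, matching the rating
period's role of absorbing the haemodynamic delay).

## Real-time decoding chain

1. **PSC**: each voxel is expressed as percent change from its mean over
   the baseline window — the fixation period for regulation runs, the
   first rest period for the decoder-training run (which has no fixation).
2. **Features**: 5 volumes × V voxels, flattened volume-major, no scaling
   or centering (amplitude information is part of the signal). Any fixed
   flattening order is equivalent for a linear decoder; it only has to be
   identical across the training and feedback paths.
3. **SVM**: soft-margin linear SVM, C = 1, label +1 = interoceptive, via
   libsvm (solver tolerance 1e-8 so that oracle comparisons at 1e-6 are
   meaningful).
4. **Platt scaling**: (A_r, B_r) maximise the Bernoulli likelihood of the
   training labels under P(y=1|f) = 1/(1+exp(A f + B)), fitted with
   L-BFGS-B on the analytic gradient (ftol 1e-12) using Platt's smoothed
   targets (N₊+1)/(N₊+2) and 1/(N₋+2), which keep the parameters finite on
   separable data. A is constrained ≤ 0 so a larger decision value always
   means a larger interoceptive probability. The Platt fit pools exactly
   the same trials as the SVM fit.
5. **Score and correctness**: condition-inverted score in [0, 100]; a
   score of exactly 50 counts as incorrect (strict threshold). Run
   summaries average the displayed (inverted) scores.

## Sham feedback model

Score "categories" are fixed-width bins (default width 10 on [0, 100]);
the fitted model stores the unconditional bin distribution, a first-order
bin-to-bin transition table counted over consecutive within-run,
within-subject score pairs, and each bin's empirical score pool (so
sampled values reproduce the marginal shape exactly). Sampling first draws
trial success from the run-specific rate, then draws a bin from the
previous trial's transition row truncated and renormalised to the
success/failure range — the unconditional distribution serves the first
trial of a session and any unobserved or empty row — and finally draws a
concrete value from the bin's pool restricted to that range. An
alternative conditioning on the binary success/failure category of the
previous trial is available (`transition_on="success"`); the bin
interpretation is the default. Whether sham recipients are yoked to single
donors or to the pooled group is a free choice; the pooled-group model is
used throughout.

The published run success rates (48.512, 58.589, 62.500 %) are the
defaults; `estimate_rates=True` re-estimates them as the fraction of
fitted scores strictly above 50 per run, which the cohort driver uses so
the sham arm mirrors whatever contingent arm it was fitted on.

## Offline beta-series MVPA

One GLM per run (least-squares-all): 24 trial regressors — 10-s boxcars at
the attention periods convolved with the canonical double-gamma HRF (peak
gamma delay 6 s, undershoot 16 s, dispersions 1, peak:undershoot 6:1,
32-s support, peak-normalised) — plus an intercept and a drift basis,
estimated by ordinary least squares on the PSC data; rest, rating and
feedback periods are unmodelled and act as the implicit baseline. An
optional least-squares-separate variant is not provided; motion regressors
are accepted as extra columns (zero for synthetic data).

Two design choices deviate from the obvious defaults, both for the same
reason:

* **Drift basis**: a discrete-cosine high-pass set with a 128-s cutoff
  (the SPM convention) instead of a single linear trend. A slow sinusoidal
  drift leaks into trial betas under a linear-only model.
* **Cross-validation folds**: the two contiguous halves of the run
  (condition alternation makes them class-balanced, 6+6 each) rather than
  an odd/even interleave within condition. An interleaved assignment has a
  4-block period (120 s in regulation runs) that resonates with residual
  slow nuisance: measured on the generator's own data, interleaved folds
  produced systematically below-chance accuracy (~0.33) while contiguous
  folds sit at chance for null data and recover signal cleanly. Contiguous
  folds also avoid placing temporally adjacent trials on opposite sides of
  the train/test split.

Online CA and offline CA are computed by deliberately different pipelines
(moment-to-moment PSC features vs. GLM-denoised betas) and are not
expected to agree numerically.

## Synthetic-data generator

Raw ROI signal of a run:

    data(t, v) = B · (1 + s(t, v)/100) + AR1(t, v) + drift(t, v)

with baseline B = 1000 (arbitrary units) and s the sum over conditions of
the condition's per-voxel pattern amplitude times the HRF-convolved
attention boxcar. Components and defaults:

* **Patterns**: per-subject i.i.d. N(0, 0.02) percent per voxel and
  condition (V = 150). The per-voxel amplitudes are deliberately far below
  1% so that *single-trial* decoding over 150 voxels lands in the
  near-chance regime the feedback task actually operates in; the effective
  multivoxel contrast, not any one voxel, carries the signal.
* **Noise**: AR(1) with ρ = 0.3 and stationary sd 1% of baseline, i.i.d.
  across voxels; one sinusoidal drift per run (period 128 s, amplitude
  0.5%, random phase per voxel).
* **Run-level state**: each run's pattern amplitude is multiplied by
  max(0, 1 + ε), ε ~ N(0, 0.35) — engagement/vigilance variability.
  Without it, between-subject variability of the CA learning effect is
  ~0.07, several times smaller than real cohorts show (~0.35), and the
  modest CA gain that incremental retraining alone produces (+0.03) would
  read as a significant "learning effect" in the sham arm.
* **Learnability**: contingent-feedback subjects scale both patterns by
  (1 + λ·r) in regulation run r; λ = 0 with probability 0.4
  ("non-learners", mirroring the commonly reported ~40% neurofeedback
  inefficiency prevalence), otherwise λ ~ N(1.0, 0.3) truncated at 0.
  Sham subjects keep λ-effects at 0 regardless of their drawn value —
  this gating *is* the operationalisation of feedback contingency; a
  variant driving growth from received scores is intentionally out of
  scope of the defaults. Learning is amplitude growth, not noise
  reduction, consistent with discriminability increasing without a change
  in mean activation.
* **Behaviour**: recorded beats follow the session heart rate (pre ~
  N(73, 9) bpm, dropping ~6 bpm post) with unit jitter; reported beats are
  recorded × clamp(perception fraction + coupling, 0, 1) plus integer
  noise (sd 1.5 beats). The perception fraction is ~N(0.55, 0.15) at
  baseline with a per-session jitter of sd 0.11; for contingent subjects
  the post-session fraction gains α × LE(CA) with α = 0.8, where LE(CA)
  is computed from the *displayed* scores (what the subject experienced);
  sham subjects gain nothing because their displayed scores carry no
  information.

The free parameters (pattern amplitude, λ mixture, state and behaviour
noise, α) were calibrated once so that replicate default cohorts reproduce
the study's qualitative pattern: a significantly positive contingent-arm
CA learning effect, a non-significant sham-arm true-score learning effect,
and a contingent-arm correlation between LE(CA) and Δ interoceptive
accuracy centred near 0.55. They are generator conventions, not empirical
claims about insula physiology.

What the generator does **not** emulate: physiological (cardiac,
respiratory) noise and its coupling to the interoceptive task, head
motion, spatial noise correlations, scanner spikes, non-stationary
learning within runs, and any context shift between the decoder-training
task and regulation runs (real run-1 generalisation is typically worse
than the generator's). Passing tests therefore show the *pipeline* is
correct and the *statistical logic* sound under the assumed signal model —
not that real data would yield these effect sizes.

## Seeds and determinism

All randomness flows from `numpy.random.SeedSequence` spawning: one cohort
seed determines subject draws, per-subject × per-run simulation streams,
sham sampling and behavioural sessions. Identical seeds give byte-identical
cohort reports.

## Problem sizes used by the test suite and acceptance script

Replicate-cohort checks run the full closed loop at the default cohort size
(54 subjects, 150 voxels) with offline MVPA disabled where it is not under
test; the sham-independence check uses 50 replicate 26-subject sham arms
(1,872 trials each); the sham-rate calibration uses 100,000 sampled trials;
oracle checks use small instances (8–14 points) solvable by a generic
constrained QP solver to high precision.

## Known limitations

* Incremental retraining makes later-run decoders better even without any
  subject learning (+~0.03 CA from run 1 to run 3 at default SNR). This is
  inherent to the design, not a bug; the sham arm's true scores carry it
  too, which is why the sham-arm "no learning" conclusion rests on the
  effect being small relative to between-subject variability.
* The Fisher r-to-z comparison uses the standard SE √(1/(n₁−3)+1/(n₂−3));
  variance-corrected variants are not implemented.
* Exported NIfTI files lay ROI voxels on a synthetic near-cubic grid; they
  round-trip through the package but carry no anatomical meaning.
* Confidence intervals for Cohen's d are not reported; the t-based CI of
  the mean is.
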