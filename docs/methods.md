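# Methods

`trialwise` implements a two-level mass-univariate analysis of epoched EEG
together with a synthetic cohort generator that makes every stage of the
analysis verifiable against known ground truth. This note documents the
models, the defaults and their rationale, the numerical choices, and what
the synthetic data do and do not establish about real recordings.

## Subject-level model

For each task, single-trial voltages `EEG(trial)` at every electrode × time
cell are regressed on trial-wise predictors:

* go/nogo: `EEG = β0 + β1·trial_type + β2·ITI + ε`, trial type coded
  go = −1, nogo = +1; inter-trial interval (seconds, centred) is a nuisance
  regressor.
* stop-signal: `EEG = β0 + β1·trial_type + β2·arrow + β3·ITI + ε`, trial
  type coded go = −1, successful stop = +1 (failed stops are excluded:
  the contrast of interest is successful inhibition vs going); arrow
  direction coded ±1.
* feedback tasks: `EEG = β0 + β1·valence + ε`. In the incentive flanker
  task valence is coded at the context level (potential gain = −1, loss
  avoidance = +1; all feedback trials retained). In the two-step task
  zero-point feedback is dropped and losses (+1) are contrasted with gains
  (−1).

Fits use iteratively reweighted least squares with Tukey bisquare weights
(tuning 4.685), scale re-estimated each iteration as MAD(residuals)/0.6745,
convergence when the largest coefficient change falls below 1e−6 (max 50
iterations). These are the standard robust-regression defaults (95%
Gaussian efficiency); robustness matters here because single-trial EEG
contains residual artifact epochs and heteroskedastic noise. The solver is
vectorised over the whole electrode × time grid (shared design, per-cell
weights); `statsmodels` RLM with the same norm serves as an independent
cross-check in the test suite, agreeing to ~1e−6 on clean data.

Before fitting, epochs (−200…700 ms around the locking event) are

1. baseline-corrected against the [−200, 0) ms pre-stimulus mean;
2. screened for improbable epochs: per (channel, time) cell a Gaussian is
   fitted across trials, each epoch is scored by its mean negative
   log-density, and epochs scoring above mean + 5 SD of the score
   distribution are dropped in a single pass. The estimator is a concrete,
   configurable stand-in for joint-probability artifact rejection;
3. smoothed with a 5-point centred moving average in time (the window
   shrinks at the edges, keeping the operator linear and mean-preserving);
4. restricted to the −100…700 ms analysis window, endpoints inclusive
   (401 samples at 500 Hz, 81 at 100 Hz).

Rejection runs before smoothing so that high-frequency artifacts are
scored undiluted.

## Group level

Per-subject b-values of the predictor of interest are tested against zero
with two-tailed one-sample t-tests (df = n − 1) at every cell, at
alpha = 0.025, corrected across all electrodes × time points with the
Benjamini–Hochberg step-up (no spatial or temporal clustering). The
critical p is the largest p-value among rejected tests (0 if none). Peaks
are the maximal-|t| FDR-significant cells inside an a-priori region of
interest and latency window, with ties broken toward earlier time points
and then montage order for determinism. Peak reports include the group
beta, t, df, p, critical p, a confidence interval at the
100×(1 − critical p)% level, and the one-sample Hedge's g
`g = J·t/√n, J = 1 − 3/(4(n−1) − 1)`.

## Moderated brain–brain regression

A subject's feedback sensitivity is summarised as the mean first-level
valence b over a named component window (defaults: feedback P3b at Pz,
500–520 ms; two-step P3 at CP1, 440–460 ms). At every cell of an
inhibition task's b-maps:

    b_inhibition = β0 + β1·x_c + β2·(x_c · m_c) + ε

with `x_c` the centred feedback score and `m_c` the centred trait
moderator (compulsivity = OCI-R sum, 0–72; negative urgency sum, 12–48).
The reference model deliberately has **no moderator main effect**; a flag
(`include_moderator_main`) adds one because the omission is unusual and
users may want the standard moderated form. Residual
df = n − 3 is used for the coefficient t-tests (n − 4 with the extra
column). Interaction maps are reported masked at an uncorrected p = 0.010;
no second-level FDR is applied.

Johnson–Neyman regions are computed in closed form: the simple slope
s(m_c) = β1 + β2·m_c with SE²(m_c) = V11 + 2·m_c·V12 + m_c²·V22 crosses
the two-sided threshold (default p = 0.01) where
(β1 + β2·m_c)² = t²crit·SE²(m_c), a quadratic whose real roots are
reported in raw moderator units and clipped to the observed range;
intervals are labelled by the simple-slope |t| at their midpoints. With
centred predictors the JN t at the moderator mean reproduces the
main-effect t exactly (tested).

Unique-variance analyses replace a trait by its raw residual from a simple
regression on the other trait; residuals have mean exactly zero and are
orthogonal to the covariate, and enter only the interaction term.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:

* **Events.** Go/nogo streams with exactly 25% nogo trials; stop-signal
  streams with exactly 25% stop trials and a one-up/one-down SSD staircase
  (initial 200 ms, step 50 ms, floored at 0) driving an independent-race
  respondent (defaults: go RT ~ N(450, 80) ms, stop process ~ N(200, 40)
  ms) — with overlapping finish-time distributions the staircase holds
  stop success near 50%; flanker streams with balanced gain /
  loss-avoidance contexts and performance-contingent outcomes; two-step
  streams with 80/20 common/rare transitions and a Gaussian-step reward
  walk reflected at +5 and −4 points (reflection by triangle-wave folding
  of the free walk; emitted points are the nearest integers, so the bounds
  are attainable). Choices are random: no reinforcement-learning behaviour
  is modelled. Inter-trial intervals are jittered uniformly on 0.8–1.2 s.
* **Traits.** (OCI-R, negative urgency) sums from a bivariate normal with
  means (12.6, 26.3), SDs (9.5, 5.9) and correlation 0.18, rounded and
  clipped to the theoretical ranges. Because clipping shifts the realised
  mean slightly, the coupling below centres the moderator at the cohort's
  empirical mean, keeping the generative contract exact.
* **Amplitudes.** A latent per-subject feedback amplitude F ~ N(4.0, 2.4)
  µV/coding-unit is expressed directly in the flanker task and with
  loading 0.7 (plus noise) in the two-step task. Inhibition amplitudes are
  `base + (coupling + moderation·m_c)·(F − F̄) + noise` with defaults
  coupling 0.54 µV/µV, moderation −0.03 per OCI-R unit, idiosyncratic SD
  2.8 µV — scales anchored to the group statistics this analysis is meant
  to produce (mean feedback b ≈ 4 µV with between-subject SD ≈ mean / g;
  inhibition b ≈ 5–6 µV).
* **Epochs.** drift (per-epoch per-channel constant, SD 2 µV) +
  amplitude × spatial template (Gaussian falloff over montage order from
  the component's centre channel) × half-cosine temporal kernel (width
  300 ms; peaks: nogo-P3 Cz 360 ms, stop-P3 P2 560 ms, feedback-P3b Pz
  510 ms, two-step-P3 CP1 450 ms) + AR(1)-in-time noise (coefficient 0.9,
  marginal SD 5 µV) mixed across channels by a random orthonormal matrix,
  with 5% of epochs scaled ×8 to exercise the robust estimator and the
  improbable-epoch screen. The default desk-scale montage has 16 named
  channels (19 in the extended montage); channel count is configuration —
  no head-model forward simulation or ocular/cardiac artifact simulation
  is attempted.

Everything is deterministic given (config, seed), via spawned
`numpy` SeedSequences.

### What the synthetic data do not show

The generator reproduces the *assumed* data-generating model: effects are
exactly low-rank (one spatial template × one kernel per task), noise is
stationary Gaussian AR(1), and trait moderation is exactly linear. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery, not robustness to violations found in real EEG (non-stationary
artifacts, correlated trait/noise structure, multiple overlapping
components, volume-conduction topographies).

## Problem sizes and numerical choices

Routine tests run desk-scale profiles (e.g. 12–40 subjects, 16 channels,
100 Hz, tens of trials per task); the full-scale profile (205 subjects, 63
channels, 500 Hz) is configuration, not a test requirement. The recovery
suite uses 100 seeded cohorts of n = 60 subjects at 16 channels / 100 Hz
with trial counts 320 (flanker), 120 (go/nogo), 40 (stop-signal and
two-step), first-level fits restricted to the region-of-interest channels
entering the second level and to a 300–560 ms window covering both the
feedback component window and the planted inhibition peak; these choices
keep the Monte-Carlo batch compact while leaving the estimand unchanged.
The recovery cohorts set the moderation slope to −0.05 per OCI-R unit: a
known negative slope large enough that a 60-subject cohort has adequate
per-seed power, so the sign-recovery property tests the pipeline rather
than the vagaries of a marginally powered design. Recovery is asserted
with 3σ Monte-Carlo intervals around the truth; a small residual
attenuation of the brain–brain slope (regression dilution from
measurement error in the windowed feedback score, reliability ≈ 0.97
under these conditions) is expected and stays well inside those intervals.

Other numerical choices: IRLS falls back to per-cell least squares if a
weighted normal-equation system is singular; cells with zero residual
scale (exact fits) get unit weights and count as converged; group t-maps
assign t = ±∞, p = 0 to zero-variance non-zero-mean cells (p = 1 when the
mean is also zero); JN boundary solving treats |a| ≤ 1e−300 as a linear
(or constant) equation; baseline windows are half-open [lo, hi),
analysis and component windows closed [lo, hi].

## Known limitations

* The improbable-epoch criterion is one concrete reading of
  joint-probability rejection; thresholding is single-pass by design.
* The second level's reference model omits the moderator main effect;
  estimates can differ from the standard moderated form when the moderator
  correlates with the dependent maps.
* Johnson–Neyman boundaries are clipped to the observed moderator range;
  open-ended reporting (e.g. "significant below score s") must be read
  together with that range.
* ITI distributions, staircase constants and outlier structure are
  plausible conventions, not fitted to any dataset.
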