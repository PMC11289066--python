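# Methods

This note documents what gazepipe computes, the assumptions behind the
synthetic-data generator, the numerical choices, and the limits of what
passing tests demonstrate.

## 1. Post-hoc bias ("midline") correction

Browser-based gaze estimators produce screen coordinates with a large,
slowly drifting systematic offset on top of heavy per-sample noise. The
pipeline treats the offset as constant within a trial and estimates it from
the central fixation period that precedes every trial:

* **Tail window.** Samples with `t >= fix_start + (1 - tail_fraction) *
  fixation_duration` enter the estimate (default `tail_fraction = 0.8`).
  The window is defined **by time**, not by sample count, so it is robust
  to the irregular sampling of webcam streams; the discarded head absorbs
  the saccade toward the cross.
* **Statistic.** The bias is the arithmetic mean of the kept samples minus
  the fixation point (`statistic="median"` is available as a robust
  alternative). `sd_x` — the within-trial SD of the kept x positions — is
  carried along as the dispersion of the corrected midline used by the
  trial-level exclusion rule. The across-trial SD of corrected midlines per
  participant can be derived from the bias table; the within-trial SD is
  what the exclusion rule consumes, since it is defined per trial.
* **Correction direction.** The estimated bias is **added to the
  geometry** — midline(s) and every AOI bound — of that trial. Gaze samples
  are never altered. The two-AOI paradigms correct only x (`axes="x"`,
  `dy = 0`); the four-quadrant paradigm corrects both axes (`axes="xy"`).
  Correction consistency (shifting geometry by `b` is equivalent to
  shifting samples by `-b`) is a tested invariant.
* **Missing estimates.** A trial with no fixation sample in the tail
  window keeps its original geometry, is flagged, and is excluded by the
  trial cascade ("no_bias_estimate") rather than crashing the run.

AOI rectangles are half-open (`[x_min, x_max) x [y_min, y_max)`), origin
top-left, y downward. A point on a right/bottom edge is outside; layout
validation enforces pairwise-disjoint AOIs, so hits are unique.

The **calibration score** is the fraction of samples during a dedicated
post-calibration fixation (3 s) that fall in a central region. The
literature does not pin down that region; the default is a square of
half-width 200 px around the screen centre and is configurable.

## 2. Exclusion cascade

Levels run strictly in order — participants, trials, samples — and within
a level rules are evaluated in a fixed order; the first rule that fires is
recorded. Thresholds phrased as "more than X%" are strict inequalities, so
boundary cases are retained.

* Participants: zero SD of both gaze coordinates across all task samples
  (a frozen estimator); identical response on every trial (when the
  paradigm records responses); > 50% of stimulus-phase samples outside
  every corrected AOI; > 50% of expected trials without data.
* Trials: missing bias estimate; corrected-midline deviation from the true
  midline above 25% of screen width (two-AOI mode) or — four-AOI mode —
  above 25% of screen height vertically **and** 37.5% of screen width
  horizontally (read as a conjunction of per-axis checks); `sd_x` above
  25% of screen width; response time outside [0.5 s, 30 s] (choice trials
  only).
* Samples: outside every AOI; optionally, live-feed-flagged samples.

Sample-level exclusion is implemented as the in-AOI denominator of the
paradigm outcomes: bias estimation runs first (it needs the raw fixation
samples), then trial flags, then the sample filter. The sensitivity
filters add, cumulatively and in hierarchical order: more than one failed
attention check, instruction screen dismissed in under 7.5 s ("more than
one" failure means >= 2), self-rated unreliable data, and the live-feed
sample drop. Each report carries retention counts whose sums are checked.

## 3. Paradigm outcomes

All outcomes are proportions of in-AOI samples; trials with an empty
denominator are missing; participants aggregate as the **unweighted** mean
of their trial proportions (neutral to trial length and standard in the
preferential-looking literature); groups aggregate as the unweighted mean
of participants.

* Cascade: window `[response - 100 ms, response)`, right-open so the
  response-coincident sample is excluded.
* Novelty: the whole 5-s test phase.
* Visual world: a 400-ms window starting `latency` after the target-word
  onset. The latency defaults to 200 ms (saccade-programming time); both
  the latency and length are configurable because the analysis window's
  placement is a design choice. Role proportions (target, three
  distractors) partition the in-AOI window samples and sum to 1.
* Time courses bin in-AOI samples at 100 ms (configurable) backwards from
  the response or forwards from the target onset, averaging trials within
  participants first, then participants; the curve's final window bins
  reproduce the scalar outcome exactly (tested).
* The paired online/lab contrast reports a one-sided paired t-test
  (lab > online), its Bayes factor, and an effect decomposition: the
  numerator ratio `(mean_online - chance) / (mean_lab - chance)` and the
  SD ratio `sd_online / sd_lab`.

## 4. Inferential layer

* t-tests use the exact Student distribution; p-values are kept at full
  precision. A zero-variance sample raises unless it sits exactly at the
  null value, where `t = 0` (so identical paired conditions give `t = 0`
  while a constant nonzero shift is degenerate; the paired condition
  comparison reports the diverging case as `t = ±inf`).
* Cohen's d = (mean − μ0)/SD. The one-sided 95% CI `[d_L; +inf)` inverts
  the noncentral-t CDF: `nct.cdf(t_obs; df, d_L * sqrt(n)) = 0.95`, solved
  by bisection to 1e-10. A Monte-Carlo simulation at n = 30 verifies ~95%
  one-sided coverage.
* JZS Bayes factors use the predictive formulation: BF10 is the ratio of
  the marginal likelihood of the observed t under a Cauchy(0, 0.707) prior
  on the standardized effect (half-Cauchy for one-sided alternatives) to
  its likelihood under the point null. Adaptive quadrature over the
  infinite domain at relative tolerance 1e-9; non-convergence raises. The
  implementation agrees with an independent fixed-order Gauss–Legendre
  oracle to 1e-4 relative and with pingouin's g-integral formulation
  (two-sided) to 1e-3, satisfies the one-sided mixture identity, and tends
  to 1 as the prior scale collapses.
* The binomial test is exact (`P(X >= k | p0)`). The binomial power solver
  has two variants: `method="exact"` (critical k at the achievable level
  <= alpha, power under the alternative; the sawtooth-aware minimal n) and
  `method="normal"`, the large-sample formula
  `n = ceil((z_alpha + z_beta)^2 p1 (1-p1) / g^2)`. For g = 0.13, alpha
  .05, power .90 the exact solver gives n = 128 (exact power at 119 is
  0.8897) while the normal variant gives n = 119 — the value a priori
  power tools commonly report for this design and the one
  `scripts/acceptance.py` uses; the discrepancy is intrinsic to the exact
  test's discreteness, not a numerical issue.
* Sequential stopping evaluates the BF after each batch (default batches
  50, then 25) against thresholds 5 and 1/5 with a participant cap.

## 5. The synthetic-data generator

The generator is the package's test bed: every downstream stage is
validated against data whose generating process is known.

**What it emulates.** Per-trial constant offset = participant-level drift
plus trial-level perturbation, both Gaussian per axis; isotropic Gaussian
per-sample noise; ~30 Hz sampling with ±20% multiplicative inter-sample
jitter; a fraction of samples replaced by uniform positions **outside**
every AOI (tracking loss / stimulus-independent wandering); an optional
live-feed flag; and a paired lab block sampled regularly at 250 Hz with
small offset and noise (a desk-scale stand-in for a 1000-Hz laboratory
tracker; proportions are invariant to the downsampling). Aim points for
"looking at an image" are uniform over the central portion of the image
(margin 0.30 per side), so with zero noise and offset every process sample
is inside an AOI.

**Preference processes.** Cascade: during the decision phase the
probability of aiming at the to-be-chosen image ramps linearly from 0.5,
starting `ramp_ms = 1500` before the response, to the participant's
`p_final` at the response (`ramp_ms = 0` = constant `p_final`); response
times are log-normal (median 2.5 s, σ = 0.45), which keeps essentially all
trials inside the 0.5–30-s filter. Novelty: familiarization gaze splits
evenly between the identical images; test-phase samples aim at the novel
image with probability `p_novel`; the novel side randomizes per trial (or
alternates by parity for deterministic tests). Visual world: uniform over
the four images until the target-word onset (drawn 4000 ± 500 ms after
sentence onset), then a 200-ms linear ramp from 0.25 to the block's
`p_target`; the analysis window starts after the ramp, so the injected
parameter is the estimand. Participant heterogeneity is Gaussian around
the nominal parameter (SD 0.15 for the two-AOI paradigms, 0.12 shared +
0.08 block-specific for the paired design), values clipped to the valid
range; these spreads are what the reported webcam effect sizes imply
(d = shift/SD).

**Calibrated defaults.** `noise_sd_px = 25`, aim margin 0.30, off-AOI
replacement rates 0.02 / 0.12 / 0.15 (cascade / novelty / vwp online;
0.005 lab), offset SDs 120 (participant) + 90 (trial) px on x with the
vertical scale 0.3 for the side-by-side paradigms and 1.0 for the
quadrant paradigm. Per-sample webcam noise magnitude is not something the
published record pins down, so these were chosen once so that the
simulated off-AOI exclusion fractions (≈ 9–15% online, ≈ 0.5% lab) and
mean absolute x-corrections (≈ 110–135 px) fall in the ranges reported
for webcam studies of this kind. The vertical-drift asymmetry is forced by
the data: with x-only correction, an uncorrected vertical drift as large
as the horizontal one would put most samples outside image-sized AOIs,
which is incompatible with the observed off-AOI rates.

**Deliberate idealisations.** The offset is constant within a trial (no
within-trial drift); noise is Gaussian and isotropic (real estimator error
is heavy-tailed and direction-dependent); the off-AOI process never lands
inside an AOI and never occurs during the fixation cross (a uniform
replacement process during fixation would shrink every bias estimate
toward zero by construction); there are no blinks, no head motion, no
screen-size heterogeneity, and the "true gaze" process is itself the AOI
aim — there is no oculomotor dynamics between samples. Passing
parameter-recovery tests therefore shows the *pipeline* is unbiased under
this model, not that real webcam data satisfy the model.

**Null calibration.** With `p = chance` the pipeline's grand mean is within
3 Monte-Carlo SEM of 0.5 (two-AOI) / 0.25 (four-AOI) at 200 simulated
participants, and the type-I error of the full pipeline + one-sided t-test
is ≈ 5% over 2000 replicates (16 participants × 6 trials each — sized so
the per-replicate t-test has a smooth participant-mean distribution while
the 2000-replicate sweep stays inside a desk-scale compute budget). For
the four-AOI null the participant heterogeneity is set to zero: preference
parameters below chance are undefined in this design, so a symmetric
spread around 0.25 does not exist.

## 6. Determinism and provenance

All randomness flows through one `numpy.random.Generator` seeded from the
config; identical configs give bit-identical datasets and byte-identical
machine-readable outputs (wall-clock time appears only in the text log).
Pipeline reports echo the effective configuration and the MD5 checksums of
any input tables. Intermediate artifacts are plain CSV and re-loadable;
the pipeline can resume from a written dataset directory.

## 7. Known limitations

* The exclusion rule "no variation in estimated gaze" is operationalised
  as exactly zero SD — the webcam failure mode it targets is a frozen
  estimate; near-frozen estimators pass it.
* The no-response-variation rule has a real false-positive rate at small
  trial counts (an honest participant may choose one side throughout).
* The four-AOI midline rule is a conjunction of per-axis limits; under a
  disjunctive reading, exclusions would be more aggressive.
* Calibration scores depend on the configurable centre region; comparisons
  across configurations are not meaningful.
* The generator's lab block models a desk-scale 250-Hz tracker; per-sample
  counts (not proportions) are therefore not comparable to a 1000-Hz
  instrument.
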