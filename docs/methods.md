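# Methods

This note documents the models, conventions and numerical choices behind
`pavpupil`, and what the synthetic data can and cannot show.

## Task model and schedule generation

A session is a sequence of 1-s tones (CS) and sucrose deliveries (US).
The design constrains inter-event intervals to the range 10–20 s with
mean 15 s; we realize this as i.i.d. continuous uniform(10, 20) draws,
the simplest distribution satisfying both printed constraints (the
distribution family is otherwise unspecified, so this is an assumption).
Contingent sessions place each US exactly `cs_duration` (default 1 s)
after a CS onset — reward immediately follows the tone — and contain
exactly `n_rewards` (default 120) CS–US pairs. Non-contingent sessions
draw the US renewal process from an independent random stream and emit
CS onsets until the session ends; their CS count therefore varies
slightly around the reward count. Sessions end at the last US plus a
10-s buffer (configurable). Dose labels (`saline`, `0.1`, `0.2`,
`0.5` mg/kg) tag sessions for the dose–response analyses.

Randomness: one root seed; stream `k` of session seed `s` is
`numpy.random.default_rng([s, k])`, with distinct constants for the CS,
US, lick and landmark streams. Experiment-level session seeds derive
from `SeedSequence([root, group, subject, session])`. Identical seeds
reproduce every file byte-for-byte.

## Licking: the bout process and the IRT mixture

The generator's lick train is an alternating renewal process:

* **pauses** end with hazard `b · g(t) · s(dose)`, where `b` is the
  baseline bout-initiation rate, `g(t)` is an event gain — the
  anticipation gain during [CS, CS+1 s) in contingent sessions, the
  consummatory gain during [US, US+1 s) in all sessions — and `s(dose)`
  is a non-increasing dose-suppression multiplier in (0, 1]. The
  inhomogeneous pause is sampled exactly by Lewis thinning.
* **bouts** have within-bout IRTs Exp(`w`) and geometric length with
  continuation probability `q` (a bout of `G` licks contributes `G − 1`
  within-bout IRTs).

With gains at 1 the pooled IRT density is exactly the normalized
two-exponential mixture `q·w·e^{−wτ} + (1−q)·b·e^{−bτ}`: the expected
fraction of within-bout IRTs is `E[G−1]/E[G] = q`, and pause-spanning
IRTs are Exp(`b`) by memorylessness. Generator and fitted model are
therefore self-consistent, which the parameter-recovery tests exploit.

A widely reproduced rendering of this model prints the unnormalized form
`q·e^{−bτ} + (1−q)·e^{−wτ}`, which does not integrate to 1 and pairs
`q` with the pause rate even though `q` is described as the within-bout
mixing ratio. We treat that as a typographical slip and implement the
normalized Killeen-style density throughout.

Defaults `q = 0.7`, `w = 8` licks/s, `b = 0.3` /s are typical of mouse
licking microstructure (≈ 7–9 Hz licking inside bouts, a bout every few
seconds of pause time). Gains default to 5 (CS anticipation) and 10
(US consummation); the dose map defaults to 1.0 / 0.6 / 0.4 / 0.2 for
saline / 0.1 / 0.2 / 0.5 mg/kg — phenomenological stand-ins for
dose-dependent suppression, not receptor pharmacology.

### Fitting

`fit_mixture` maximizes the mixture log-likelihood by EM with
multi-start initialization (three quantile-split heuristics plus five
randomized splits; seeded, hence deterministic). Identifiability is
enforced by relabeling so `w > b`. Convergence: relative log-likelihood
change < 1e-10, max 2000 iterations; non-convergence is flagged in the
returned diagnostics, never silent. The configurable floor of 50 IRTs
rejects samples too small to separate two exponentials.

The Bayesian mode (`method="bayes"`) samples the posterior with emcee
(24 walkers, 1500 steps, 500 burn-in by default) under q ~ Uniform(0,1)
and half-normal priors on `w` and `b` (scales 20 and 5 s⁻¹,
log-parameterized with the Jacobian), relabels swapped samples, and
reports the posterior median. MLE is the default because it is
deterministic and directly testable; the two agree on simulated data.

### Classification and segmentation

An IRT is within-bout iff `q·w·e^{−wτ} > (1−q)·b·e^{−bτ}`; ties label
pause (conservative bout onsets). This equals thresholding at
`τ* = ln(q·w/((1−q)·b))/(w − b)`; if the log argument is ≤ 1 every IRT
is a pause. Bouts are maximal runs of within-bout IRTs; runs shorter
than `min_licks_per_bout` (default 2 — a single lick has no within-bout
IRT) are excluded from onset lists but counted, so lick totals are
conserved.

## Pupil: ellipse fit, validity, standardization

Each frame's confident landmarks (likelihood ≥ 0.9 by default) feed a
direct least-squares conic fit constrained to ellipses (scikit-image's
`EllipseModel`, the routine this measurement chain conventionally uses),
called on centered, rms-scaled coordinates for numerical stability and
mapped back. Area is `π·a·b` from the fitted semi-axes, not from a
pixel mask. Degeneracy screening: points on an exact conic make the
6-column design matrix rank-5 by construction, so the screen rejects a
*second* near-null direction — ratio of largest to fifth singular value
above 1e8 (default) raises a degenerate-geometry error; fewer than five
usable points raises an insufficient-points error.

Frames failing these checks are invalid. Invalid runs no longer than
`max_gap_s` (default 0.5 s, covering ordinary blinks) flanked by valid
frames are linearly interpolated and flagged; longer runs stay invalid
and propagate to trial exclusion rather than being bridged. How blinks
were handled upstream of standardization is not specified in the
measurement chains this mirrors; the masking rules here are this
package's own convention, chosen conservatively. Standardization is the
per-session z-score over valid frames with the sample (n−1) sd, matching
the conventional `scale` behavior; constant traces raise rather than
return zeros.

The landmark generator emits the latent radius as baseline (30 px) plus
difference-of-exponential kernels at CS (contingent group only — the
non-contingent group shows no CS-evoked response, which the null tests
require), US and bout onsets, a small negative pre-bout dip (0.5 s
before onset) mirroring the pre-bout constriction seen in bout-aligned
averages, and AR(1) drift (sd 0.8 px, τ 30 s). Kernel amplitudes
(1.5 / 2.0 / 1.0 / −0.5 px) are configuration, not claims about effect
sizes. Landmarks sit at 45°-spaced angles with Gaussian jitter
(0.5 px); blinks collapse points toward the eyelid line and drop
confidence below 0.5.

## Alignment and window statistics

All intervals are half-open `[t0, t1)`: every lick maps to exactly one
bin, and a US exactly at CS offset (the contingent design) is *not* a
CS/US overlap. Licks are binned to rates; pupil z is linearly resampled
at bin centers from valid frames. Trials whose [−3, +3) window leaves
the recording, or (pupil) touches a remaining invalid gap, are dropped
and counted. Window anchors: Pre = [−1, 0) before CS onset, CS = [0, 1)
from CS onset, US = [0, 1) from delivery time (in the contingent design
delivery time and CS offset coincide; we anchor at delivery). The
pre/post difference score is mean over [0, +3) minus mean over [−3, 0),
per trial, averaged per session. Bout-onset analyses retain an onset
iff no CS onset or US time lies in the *open* interval (onset−3,
onset+3) s.

Mixed-model fitting on the tidy window table is delegated to
statsmodels MixedLM (REML), default formula
`lick_rate_hz ~ C(window, Treatment('Pre')) * C(group)` with
subject-level random intercepts and window slopes; if that maximal
structure fails to converge the fit retries with random intercepts only,
the usual simplification. REML, degrees-of-freedom approximations and
Tukey-adjusted contrasts are deliberately out of scope.

## Problem sizes and runtime choices

Tests and the acceptance checks run at desk scale as this package's own
defaults for simulation studies: schedule-level checks use full 120-
reward sessions (cheap); pipeline-level effect/null contrasts use 50
sessions per arm of 20 rewards at 10 Hz landmark video, enough for the
sign test and SEM bounds while keeping per-frame ellipse fitting modest;
bout-model recovery uses 20 replicates of 5,000 pooled IRTs. Full-scale
sessions (120 rewards, 30 Hz) run through the identical code paths.

## What the synthetic data does and does not show

The generator matches the *structure* the analysis assumes — renewal
schedules, mixture-distributed IRTs, event-locked pupil kernels,
multiplicative dose suppression — so passing tests demonstrate that the
measurement chain recovers known ground truth under that structure:
correct schedule constants, exact ellipse round trips, < 10% parameter
recovery error, contingent-only CS contrasts, ≈ 6.7% overlap. It does
not emulate real videos (no pixel data, occlusions or gaze shifts),
real lick-sensor artifacts, learning across sessions (anticipation is
stationary within a session), individual differences beyond seed
variation, or receptor-level pharmacology. Consequently, passing tests
validate the software and its statistical procedures, not any empirical
claim about mice; group-level effect sizes here are configuration, and
real-data mixed-model statistics are intentionally not reproduced.

## Known limitations

* The EM fit can sit at the `w ≈ b` boundary on genuinely
  single-exponential data; diagnostics expose this (log-likelihood
  equals the single-exponential maximum) but no formal model-comparison
  test is built in.
* Pupil-trace interpolation is linear and short-gap only; saccade- or
  luminance-driven artifacts other than blinks are not modeled or
  corrected.
* The bout segmentation assumes the fitted stationary mixture applies
  session-wide; within-session nonstationarity (satiety) biases `b`
  upward when event gains are active.
* Non-contingent CS counts are not exactly 120; analyses treat CS count
  per session as data, not a constant.
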