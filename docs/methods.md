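# Methods

## Problem setting

In monitor-guided (endoscopic / minimally invasive) procedures the operator
watches a screen while manipulating instruments, so the coupling between
gaze behaviour and hand kinematics is itself a trainable skill.  `gazehand`
implements an analysis pipeline for assessing that coupling from two
synchronised recordings per session: a binocular gaze stream (screen-pixel
coordinates, nominal 60 Hz, top-left origin on a 1920×1080 display) and a
3-D hand trajectory from a haptic interface (tool and camera channels,
nominal 100 Hz, device length units).  A session consists of up to ten
repetitive tasks of at most 10 s each.

## Event model

Both signals are reduced to the same three-way interval labelling:

* **stable** — the signal stays nearly stationary: a *fixation* for gaze, a
  *stand-still* (idle hand) for the hand trajectory;
* **rapid** — a fast relocation: a *saccade* for gaze, a *sudden sharp
  movement* for the hand;
* **gap** — no usable signal: blinks / track loss for gaze, non-finite
  samples for the hand.

Each inter-sample interval `[t_i, t_{i+1})` is labelled (gap when either
bounding sample is invalid, otherwise by comparing the finite-difference
speed `‖x_{i+1}−x_i‖/(t_{i+1}−t_i)` to a threshold), and runs of equal
labels become events.  The resulting sequence is an exact partition of the
classified window, which makes downstream per-task accounting exact.

### Adaptive velocity threshold

Fixed velocity thresholds do not transfer between signals: gaze in pixels/s
and hand motion in device-units/s live on unrelated scales, and individuals
differ.  The classifier therefore estimates a threshold per signal (per eye
for gaze): starting from `θ₀ = mean + k·sd` over all speeds, the mean and
standard deviation are recomputed over sub-threshold speeds only and
`θ ← mean + k·sd` is iterated until the update falls below a tolerance
(defaults: `k = 3`, tolerance 1 unit/s, ≤ 50 iterations, with a small
positive floor for degenerate constant input).  On noise-only input this
converges to the fixed point of the truncated-moment map, which the test
suite checks against an independent truncated-normal computation; on
noise + fast-movement mixtures it settles between the modes.

Because the threshold is a homogeneous function of the data, uniform
spatial rescaling leaves the labelling unchanged, and because the speed
(not the per-sample displacement) is thresholded, the labelling is
sampling-rate independent.  Both properties are enforced by tests.

**Operating regime.** A mean+k·σ exclusion step can only carve off the fast
mode when it is a minority of the samples: with a narrow fast mode making
up fraction *p* of the speeds, the first iterate falls below the fast mode
iff `p + k·√(p(1−p)) < 1`, i.e. *p* < 0.1 for k = 3.  Velocity-threshold
classification in general presumes that rapid movements occupy a small
share of recording time; inputs violating that (e.g. near-continuous
motion) leave the threshold above the movement mode and everything is
labelled stable.  The synthetic generator's defaults respect this regime.

### Binocular rule

For gaze, speeds and thresholds are computed per eye and an interval is
stable only if **both** eyes are sub-threshold (conjunction; a disjunction
variant is available via config).  Conjunction reflects the intent of using
both eyes' evidence and is robust to monocular artefacts at the cost of
occasionally splitting fixations; either-eye invalidity marks a gap.

### Minimum-duration refinement

Raw label runs are refined with two physiologically motivated rules, then
same-kind neighbours are merged: stable runs shorter than `min_stable_ms`
(default 50 ms ≈ 3 gaze samples at 60 Hz) are relabelled rapid, and rapid
runs shorter than `min_rapid_ms` (default 10 ms) flanked by stable runs on
both sides are absorbed into them.  Gaps never change kind and never merge
with non-gap runs — a stable run split by a gap counts as two events, the
conservative choice.  The full rule semantics are pinned down by an
exhaustive brute-force equivalence test over every ternary label sequence
up to length 12.

A consequence worth stating explicitly: within a gap-free window the final
sequence alternates stable/rapid, so the two counts can differ by at most
one.  Only gaps decouple them (two rapid events separated by a gap, or two
stable events separated by a gap alone).

## Metrics

Six quantities per participant-task, computed from events clipped to the
half-open task window (an event straddling a boundary contributes its
clipped duration, counted once in the segment containing its midpoint):

| metric | definition | units |
|---|---|---|
| FD  | mean fixation (eye stable) duration | ms |
| FN  | fixation count | – |
| SN  | saccade (eye rapid) count | – |
| SSD | mean stand-still (hand stable) duration | ms |
| SSN | stand-still count | – |
| SSM | sudden-sharp-movement (hand rapid) count | – |

FD/SSD are *missing*, not zero, when the count is zero (zero would bias
means downward), and missing values are excluded from aggregation.
Aggregation is per task → mean per participant → group mean and sample SD
(ddof = 1; a single-participant group reports SD 0, flagged via `n`).

## Statistics

For each skill group and each pair FD–SSD, FN–SSN, SN–SSM: Shapiro-Wilk
normality on both vectors gates the method — Pearson when both p > .05,
Spearman (mid-ranks) otherwise; constant vectors fall back to Spearman with
a warning.  Coefficient magnitudes are labelled with Cohen's bands as
small `[0, 0.3)`, moderate `[0.3, 0.5)`, strong `[0.5, 1]` (band edges
chosen so that every published labelling convention instance we mirror,
including a coefficient of .06 labelled small, is reproduced).  Two-sided
p-values throughout; no multiple-testing correction and no outlier
exclusion (an optional report flags |z| > 3 values without removing them).
The correlation unit is configurable: `participant` (each point is a
participant's mean over tasks — the small-n design) or `task`
(participant-tasks; used by the recovery analyses, where n = 100 per
cohort makes band recovery statistically stable).

Group comparison uses a Mann-Whitney U with mid-ranks: `U = min(U₁, U₂)`,
per-group mean ranks, a tie-corrected normal-approximation z and two-sided
p, and an exact permutation p (probability of a min-U at least as extreme
over all group assignments) by default when n₁+n₂ ≤ 12.

## Synthetic cohorts

The generator plants eye-hand coupling at the per-task metric level with a
Gaussian copula: a 6-dimensional latent normal with unit diagonal and the
three pair couplings as off-diagonal entries, mapped through fixed monotone
transforms to metric targets (shifted-lognormal for durations, rounded
linear for counts; latents clipped at ±3 so layouts always fit the 10 s
window).  Default profiles: intermediate (−0.8, −0.8, +0.8), novice
scenario-1 (+0.45, +0.45, +0.55), novice scenario-2 (−0.45, −0.45, +0.10) —
signs and bands mirroring the qualitative skill-group pattern, not any
specific numeric table.

A task plan lays the targets out as alternating stable events and
separator slots.  Because alternation ties the counts (see above), the
independent FN/SN and SSN/SSM draws are realised with short signal-loss
windows (120 ms): a slot with a surplus of rapid events splits them with
gaps (blink mid-saccade / tracker dropout mid-movement), and a slot with no
rapid event is a gap alone (gaze or tool simply elsewhere when the signal
returns).  Tasks are separated by 300 ms loss windows (scene reset), so
consecutive tasks never share an event.  The planted metrics recorded per
task are exactly those implied by the final layout; recomputing metrics
from the ground-truth event sequence reproduces them identically (tested).

Rendering: fixations/stand-stills jitter around their centroid; saccades
are constant-velocity lines of fixed 150 px amplitude over 50 ms; hand
transports are cosine-ramp moves of fixed 40-unit amplitude over 60 ms;
sample clocks carry ≤ 0.6 ms timing jitter; the two eyes carry an 8 px
vergence offset and independent jitter phases; the camera channel is a
passive echo of the tool and not classified by default.

**Noise model.** Stable-event jitter is band-limited oscillation (two
drift/tremor sinusoids, 4.1/9.7 Hz for gaze at 0.5 px RMS, 2.9/6.1 Hz for
the hand at 0.3 units RMS) rather than white noise.  Oscillatory jitter has
a *bounded* instantaneous velocity, so the adaptive threshold's fixed point
sits strictly above the noise speeds and count recovery is exact; and its
velocity distribution is sampling-rate invariant, which is what makes the
60 Hz vs 100 Hz rate-independence check meaningful.  White measurement
noise has neither property (its finite-difference speeds scale with the
sampling rate and have unbounded tails), so real tracker data will show
occasional fixation splits that the synthetic streams do not — passing
recovery tests demonstrate correctness of the event accounting, not
immunity to heavy-tailed sensor noise.

**Magnitudes.** Defaults per ≤ 10 s task: FD ≈ 330–900 ms, FN ≈ 4–16,
SN ≈ 0–12, SSD ≈ 450–930 ms, SSN ≈ 3–13, SSM ≈ 0–10, task durations
≈ 5–8 s (tasks completed before the 10 s timeout).  These keep rapid
intervals ≈ 5–8% of each signal — inside the threshold's operating regime
derived above.  Field reports from real endoscopic-training recordings can
show far larger saccade/sharp-movement counts per interval; such
compositions are outside the regime of any adaptive velocity threshold of
this family and are not emulated.

## Numerical and design choices

* Time is milliseconds from stream start; all intervals half-open
  `[t_start, t_end)`, so partitions are exact.
* Alignment applies a signed offset to the hand clock (`auto` = align first
  timestamps) and intersects the covered ranges; no resampling, no drift
  estimation (sessions are minutes long).
* Threshold comparison is strict (`speed < θ` is stable); thresholds are
  floored at 1e-6 units/s; all-identical speeds return the floor/mean,
  flagged converged.
* Velocity median filtering (3-sample) exists but is off by default so the
  classifier output is exactly reproducible from the rules above.
* CSV I/O parses floats in round-trip mode; read∘write is the bitwise
  identity on valid streams.
* Cohort simulation derives one child seed per participant from a single
  `SeedSequence`, so cohorts are bit-reproducible and participants
  independent.

## Known limitations

* No smooth-pursuit or glissade classes; no dispersion-based alternative;
  no saccade main-sequence modelling (position accuracy of saccades at
  60 Hz is limited anyway).
* The hand metrics default to the tool (dominant-hand) channel; the camera
  channel can be classified on request but has no dedicated metrics.
* The Mann-Whitney normal approximation is coarse below n ≈ 10 per group;
  use the exact permutation p there (the default for pooled n ≤ 12).
* Whole-scenario (unsegmented) analysis is available but per-task windows
  are the tested path.
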