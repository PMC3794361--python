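# Methods

This note documents the models, conventions and numerical choices behind
`fishrig`, and what the simulation-based tests do and do not establish
about real rigs.

## Variance detection

Presence of a fish inside a region of interest (ROI) is decided from the
**population variance** (divide by *N*) of the pixel intensities in the
ROI rectangle. Population rather than sample variance was chosen because
it is exactly invariant under a uniform additive intensity shift and the
convention is immaterial in practice: thresholds are operator-set on the
same statistic they are compared against. ROIs are axis-aligned
rectangles, 0-based, half-open, with at least 2 pixels.

The Schmitt trigger uses strict inequalities: detect when
`variance > T`, release when `variance < h·T` with hysteresis fraction
`h = 0.8` by default (configurable per ROI). Values exactly on a boundary
do not transition. Every ROI starts VACANT at stream start. Color frames
are converted to grayscale by an unweighted channel mean; the camera
modeled is black-and-white, so this path only serves fixture files.

`suggest_threshold` replaces interactive threshold setting: it returns the
midpoint between the `vacant_fraction` quantile of a recorded variance
trace and the trace maximum. The midpoint keeps the release level `0.8 T`
above vacant-state noise whenever the vacant and occupied variance bands
are separated by more than a factor ~2.5, which holds by orders of
magnitude for a dark fish on a bright background. A trace with no
separation (constant, or all-vacant) is rejected rather than guessed at.

## Synthetic scenes

The fixture generator emulates the rig's imaging conditions: a flat
bright background, a *global* (spatially uniform) illumination offset per
frame, i.i.d. Gaussian "ripple" pixel noise, and the fish as a dark
30×5 px horizontal streak stamped at a scripted trajectory position.
Values are clipped to [0, 255]; a fixed seed makes the frame sequence
bit-identical. It deliberately does **not** model: spatially *non*-uniform
shadows crossing an ROI boundary, specular reflections, water-surface
lensing, fish-shape deformation, or partial ROI occupancy at an angle.
Passing tests therefore show the detector logic is correct under the
uniform-illumination assumption the design rests on; they do not show the
assumption holds on any particular physical tank — that remains an
operator-side check when thresholds are set.

## Session controller

All times are quantized to the frame clock (1/fps s; fps defaults to 50).
Key timing conventions, where the protocol narrative leaves them open:

* The 1-min hold applies once at session start; later trials are
  separated by the 20-s ITI (after reward) or the 20-s timeout (after
  other outcomes).
* The gate is modeled as instantaneous, but apertures become accessible
  `gate_latency_s` (default 0.5 s, under the <1 s the hardware needs)
  after the GATE_UP command; the PSI runs from that moment.
* An "entry" is the ONSET edge of a detection event. A fish already
  inside a region when a response window opens does not count until it
  leaves and re-enters — this mirrors the detector's re-trigger rule and
  removes an ambiguity about pre-positioned fish.
* Anticipatory classification is by time alone: any aperture onset during
  the PSI ends the trial, regardless of which aperture.
* On a correct response, food is delivered at the first magazine onset
  after the response and the gate closes at that same moment ("as the
  fish passes through"). If the fish never returns before session end the
  trial stays CORRECT with no delivery.
* Magazine-training sessions open with one dark gap (a settling period)
  before the first illumination; if no entry occurs during the up-to-10-s
  illumination the light simply goes off and the 30-s gap begins.
* Habituation delivers food on the first magazine entry, then on any
  entry at least `habituation_food_interval_s` (30 s) after the previous
  delivery.
* The stimulus position is drawn uniformly from {1..5} per trial with a
  seeded RNG, repeats allowed; no balancing is imposed.
* Sessions terminate on the clock (`session_length_s`, default 1800 s); a
  trial whose outcome is undecided at expiry is discarded.

The controller's event-file handoff to the original hardware loop is
replaced by an in-process event stream; logs (trials, raw events,
commands, metadata) round-trip bit-exactly through CSV/JSON, with floats
serialized via `repr`.

## Fish agent

The agent is a generative model of trial behavior, not of swimming or
learning:

* **Premature entries**: homogeneous Poisson hazard `λ` (per second)
  during the PSI — the simplest model in which anticipatory probability,
  `1 − exp(−λ·PSI)`, increases with PSI length. Default λ = 0.05/s,
  giving ~22% premature trials at a 5-s PSI and ~39% at 10 s.
* **Response**: with probability `p_respond` (default 0.95; omissions are
  empirically rare) the agent responds at a log-normal latency (median
  5 s, σ = 0.5 — positive and right-skewed, resampled into the 30-s
  window), choosing the lit aperture with probability `p_correct`
  (default 0.6, matching typical adult-zebrafish discrimination accuracy)
  and otherwise uniformly among the other four.
* **Reward collection**: log-normal magazine-return latency (median 3 s).
* **Speed–accuracy coupling** (optional, off by default):
  `p_correct` becomes a logistic function of the sampled latency with
  slope `speed_accuracy_beta`, anchored so the median latency keeps the
  configured accuracy.
* **Cohorts**: per-fish λ is drawn from a gamma distribution (shape 2,
  scale 0.025 → mean 0.05/s), producing the right-skewed between-fish
  distribution of anticipatory responding typical of mutagenized screens.

The agent emits quantized detection events *and* the trial record it
expects the controller to produce, derived by applying the controller's
own classification windows to the quantized event times. The closed-loop
identity — controller output equals agent expectation on every trial —
is therefore a two-route consistency check between an event-driven state
machine and a per-trial generative bookkeeping, not a tautology.

`recover_hazard` maximizes the binomial likelihood of anticipatory counts
under `p(PSI) = 1 − exp(−λ·PSI)` over λ ∈ [0, 100] with a bounded scalar
minimizer (`xatol = 1e-10`); zero anticipatory responses give the boundary
estimate 0 with a warning, and an all-anticipatory dataset is reported as
unbounded. At 2,000 trials per PSI the Fisher information puts the
relative standard error of λ̂ near 3%, so the 10% recovery tolerance used
in the tests is ~3.5 standard errors.

## Metrics

Proportions follow the standard formulas exactly; any zero denominator
yields NaN (undefined), never 0. The attrition criterion is strict:
retained requires mean trials/session **> 10**, averaged over all 5-CSRTT
sessions attempted. Learning slopes are plain OLS of reinforcers against
1-based session index. The phase contrast averages a chosen metric over
the last *k* sessions at the lower PSI and the first *k* at the higher
PSI (k = 4 by default, clamped to what was actually run in the bundled
pipeline); model fitting on the exported long-format tables is left to
external statistics software.

## Problem sizes

The test suite and acceptance script run everything at desk scale: random
ROIs up to ~40×50 px, fixture videos of 250–2,000 frames at reduced
resolution and frame rate (the vision round trip uses 5 fps and a
100×200 px scene, streamed frame by frame), 100 closed-loop sessions, and
2,000 trials per PSI condition for the hazard analyses. These sizes give
3-standard-error statistical checks sub-percent to few-percent resolution
while keeping the full suite in the seconds-to-minutes range.

## Known limitations

* No background subtraction or trajectory tracking outside the ROIs — by
  design, as whole-tank tracking is unreliable under uncontrolled ambient
  lighting.
* The agent has no within-session or across-session learning dynamics;
  acquisition curves must be imposed through per-session parameter
  schedules if needed.
* The trajectory bridge teleports the fish between regions (positions are
  only meaningful inside ROIs during events), so it cannot be used to
  study swim kinematics.
* Attention manipulations via shortened stimulus durations are supported
  by the schedule but have no validated agent parameterization.
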