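# Methods

`apisim` models a closed-loop aversive visual-conditioning assay for walking
honeybees and implements the full analysis pipeline for the position/event
logs such an assay produces.  This note documents the model, its parameters,
the numerical conventions, and the limits of what the synthetic data can
show.

## The assay

A bee walks freely in a linear chamber (default 26 cm, 26 infrared sensors,
16 Hz position sampling).  Each half of the chamber can be lit independently
by one of three narrow-band LEDs — blue (465 nm), green (525 nm), yellow
(590 nm) — and carries an electrifiable grid.  A trial lasts 14 s with 44 s
from onset to onset.  At onset the controller reads the bee's position: the
half containing the bee receives the danger light λ+, the other half the
safety light λ− (or darkness).  In reinforced protocols, 10 V / 100 ms
pulses at 4 Hz begin 3 s after onset and end with the light at 14 s — 44
scheduled pulses — and are delivered only while the bee is on the λ+ side.
Because λ+ follows the bee and shocks are escapable, the paradigm is
operant: the bee controls its own punishment.

Protocol builders cover the four standard designs: (I) 9 training + 4 test
trials for each of the six ordered color pairs; (II) 9 training trials plus
a six-probe test battery (passive-avoidance probe with λ− on the bee side,
trained lights against an untrained third light, and each light singly
against darkness, delivered as pseudorandomized single-color and dual-color
triplets); (III) an unreinforced intensity-preference series — a reference
light fixed at 100% against a test light swept 0–100% in 10% steps, one
descending and one ascending series, each level presented reciprocally with
the reference first on and then off the bee side (44 trials); (IV) as I but
with a single preference pre-test and the green intensity rebalanced to the
measured equal-preference points (62% against blue, 46% against yellow).

## Behavioral metrics

* **Preference Index.**  PI = (t_safe − t_focal)/(t_safe + t_focal) over
  the 14 s stimulus window, occupancy accumulated per 16 Hz sample
  (rectangle rule; error bounded by one sample).  The *focal* stimulus is
  λ+ in conditioning trials, the bee-side light in test probes, and the
  100% reference in the intensity series (so preference curves start near
  −0.5 at test intensity 0 and rise through 0 at the balance point); the
  orientation is exposed as a sign parameter.  Samples exactly on the
  midline count as left — the same tie-break the closed loop uses.  The
  denominator is summed occupancy, which equals the stimulus duration
  unless samples were dropped.
* **Shock counts.**  Actual = logged deliveries.  Fictive = replaying the
  44-pulse schedule against the recorded trace and counting pulses whose
  nearest *preceding* sample (causal) lies on the focal side.  On
  reinforced trials the fictive recount equals the logged count exactly,
  because delivery decisions in the simulator are made on the same
  sensor-quantized positions the trace stores; this oracle equivalence is
  asserted over ~1,000 simulated trials.
* **Speeds.**  Speed over a window is summed |Δposition| divided by the
  window length, endpoint samples included (a constant-speed walk returns
  its speed exactly).  Pre/post speeds use the 3 s windows flanking light
  onset; ΔSpeed is first-test-trial minus first-training-trial speed,
  separately per window, also as a percentage of the training value.
* **Exclusion.**  Bees averaging strictly below 2 cm/s over the test
  trials (full 14 s window) are flagged exhausted and excluded from group
  summaries while remaining in the raw tables.  The averaging window is a
  package choice recorded in the analysis metadata; for pure preference
  protocols the preference trials serve as the assessment trials.

Group summaries are per-(paradigm, protocol, phase, trial) mean ± SEM over
non-excluded bees, compared with one-sample t-tests (PI against zero) and
Welch two-sample t-tests.  Welch is used because the assay's group
variances are not known to be equal.  Mixed-effects trajectories (bee as a
random effect) are deliberately out of scope; per-bee summaries feed the
t-tests instead.

## Intensity-preference curves

Per-pair preference is summarized by unweighted least squares on the
per-intensity mean PI (pooled over both series directions and both
reciprocal presentations): y = a + b·x/(c + x) with c > 0, initialized at
a = y(0), b = y(100) − y(0), c = midrange.  The zero-preference intensity
is the closed form x0 = −a·c/(a + b), reported only when a and a + b have
opposite signs and x0 ∈ (0, 100]; otherwise one light is preferred over
the whole tested range and x0 is none.  The closed form is cross-checked
against a bracketing root-finder to 1e−9.  Degenerate (constant) data
return the flat fit rather than an error; non-convergence is flagged.
When the measured curve is nearly linear over 0–100%, b and c are jointly
ill-determined (b, c → ∞ with b/c fixed) but x0 remains stable.

## The synthetic bee

No individual-level behavioral model is published for this assay; the
agent here is the package's own construction, with one contract: every
downstream metric is exercised, and the assay's headline group patterns
are reproduced qualitatively.  The agent is a persistent random walker
whose direction flips each 1/16 s sample with probability

    p_flip = (1 − persistence) + crossing_gain · (U_behind − U_ahead)

clipped to [0, 1], where each half-chamber's utility is

    U = a(λ, I) − max(0, V(λ) − s(λ))

* a(λ, I) = A_λ · I/(I + h): saturating phototactic attraction, A_B = 0.85,
  A_G = 1.0, A_Y = 0.75, half-saturation h = 40%.  The ordering makes green
  the innately preferred light and places the equal-preference intensities
  of green near 62% (vs blue) and 46% (vs yellow).
* V(λ): acquired aversion, updated per *delivered* pulse by the
  Rescorla–Wagner rule V ← V + α(V_max − V) with α = 0.03, V_max = 1 —
  tying acquisition to experienced punishment, which is what makes the
  contingency operant.
* s(λ): a subtractive safety prior on *expression*: s_B = s_Y = 0.55,
  s_G = 1.2 > V_max.  Green aversion is therefore acquired but never
  expressed as place avoidance — the asymmetry at the heart of the assay —
  while the anticipatory speed response (below) still develops, because it
  reads the raw V.

Shock pulses additionally (i) multiply walking speed by 1.5 for the
remainder of the pulse train, (ii) add an acute escape drive of 2.0 to the
utility deficit of the electrified side *while the bee stands on it*, and
(iii) drive the V update.  Step speeds are |N(4, 1)| cm/s, scaled by
1 + 0.35·max V over the lights present while lights are on (anticipation).
Boundaries reflect.  Positions are quantized to the sensor pitch before
logging, and every side decision (onset resolution, pulse delivery) is made
on the quantized value so analysis re-derivations match the log exactly.

Parameter choices that were genuinely open, and why they were fixed as
they are:

* **persistence = 0.995** (mean run ≈ 6 s, about one chamber length).
  Slower mixing leaves a large start-side occupancy bias — PI is measured
  from the moment λ+ is placed on the bee's own side, so any walker that
  lingers shows spuriously negative PI.  Observed unreinforced bees show
  PI ≈ 0, which requires near-ballistic shuttling.  A small residual bias
  (≈ −0.03) is unavoidable at finite speed.
* **crossing_gain = 0.015** reproduces moderate group preferences
  (training PI ≈ 0.2 for reinforced blue-λ+ cohorts, |PI| ≈ 0.4 for a
  100% light against darkness) rather than absorbing walks.
* **escape drive local, not remote.**  Applying the pain term to the
  electrified side regardless of the bee's position made even naive agents
  near-perfect avoiders (trial-1 shock counts ≈ 9 instead of ≈ 14–19) and
  gave green-λ+ cohorts strong training preferences, contrary to the
  assay's findings; the local form lets untrained bees return and collect
  pulses, as real bees do.

The inner simulation loop is an inlined version of `step_agent` using
pre-drawn random arrays (a 36-bee cohort simulates in ~2 s); `step_agent`
remains the reference single-step API.  The two differ in one documented
respect: the loop sustains the escape drive between pulses of a train,
while `step_agent` applies it only on samples flagged `pulse_active`.

### What the synthetic data do and do not show

The generator reproduces, at fixed seeds and n ≈ 30–36 per group: rising
PI and falling shock counts across nine training trials for blue/yellow
λ+ with flat unreinforced controls; acquired-but-unexpressed aversion for
green λ+ (flat/negative PI, sustained shocks, intact speed anticipation);
positive ΔSpeed in the post- but not the pre-onset window for reinforced
bees only; and intensity-preference curves crossing zero near the balanced
intensities.  It does **not** reproduce the exact published group values
(PI magnitudes, trial-1 shock counts ≈ 19, the specific x0 values of real
bees), and it omits thigmotaxis, wall-following, grooming pauses,
alarm-pheromone effects, photoreceptor adaptation and any flight behavior.
Passing tests therefore validate the pipeline's arithmetic and the
qualitative adequacy of the closed-loop model, not quantitative predictions
about real bees.

## Problem sizes and numerics

The test suite and the acceptance script run cohorts of 12–36 bees per
group (the assay's own per-protocol group sizes were 28–36) and one
112-bee cohort for the 1,000-trial oracle-equivalence check; the
Monte-Carlo calibrations use 200 curve-fit replicates and 10,000 t-test
replicates.  All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning, so identical (protocol, parameters,
seed) triples give byte-identical logs.  Curve fits use tolerances 1e−12
(trust-region least squares); the closed-form/numeric x0 agreement is
asserted at 1e−9.  Time intervals are half-open [t0, t1) throughout except
speed windows, which include both endpoint samples; positions are 0-based
cm from the left end; the midline belongs to the left half.
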