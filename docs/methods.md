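# Methods

## Scope and architecture

`personasim` simulates the behaviour-regulation loop of an embodied
conversational agent at the command level: it ends where an animation
engine would begin, emitting a Behavior Markup Language subset rather
than rendered motion. The architecture is hybrid. A continuous component
integrates the agent's affective state at a fixed tick; an event-based
component (a finite state machine) runs the turn-taking logic of a
rock-paper-scissors game. Both feed behaviour controllers (face, gaze,
gesture/posture) whose proposals are arbitrated by an attention
controller and a priority scheduler before being logged as scheduled
commands. Personality enters twice: in the constants of the affect
dynamics, and in the selection/execution parameters of every controller.

Personality is handled as five discrete categories — the corners of the
Extraversion × Emotional-Stability plane (HELS, HEHS, LELS, LEHS) plus a
Neutral midpoint. Continuous trait pairs in [−1, 1]² are accepted but are
immediately discretized (quadrant sign, with an inclusive neutral band of
half-width 0.2 on both axes); no interpolation between category parameter
sets is attempted, because the five discrete settings are the object of
study.

## Affect dynamics

State: valence V and arousal A, both clipped to [−1, 1]. Update per tick
(explicit Euler, dt = 0.1 s default):

```
V ← clip(V − γ(V − V₀)dt + Σ s·g(s)·w(n)·m + σ√dt·ξ),  ξ ~ N(0,1)
A ← clip(A − γ(A − A₀)dt + Σ s·g_A·w(n)·m)
```

* γ (`decay_rate`) = 0.05 s⁻¹: slow enough that a single game event
  colours the next ~20 s of expression, fast enough that the state
  re-equilibrates between rounds.
* Baselines (V₀, A₀) per category implement the "initial value" table
  rows: positive = +0.3, negative = −0.3, zero = 0.
* Reaction gains g(+)/g(−) (valence) and g_A (arousal) take the ordinal
  values High = 2.0, Normal = 1.0, Low = 0.5 — symmetric ratios around
  the Neutral value so every printed ordering is scale-free.
* Need weights w: safety 1.0 > belonging 0.6 > esteem 0.3, the Maslow
  ordering of trigger impact.
* Lability σ (High 0.03, Normal 0.01, Low 0.0, in valence units·s^-1/2)
  produces the spontaneous valence fluctuation of the emotionally
  unstable categories. It acts on valence only.
* Clipping (not a sigmoid) enforces the bounds so the interior dynamics
  stay linear, matching the stated linear-with-impulses form; the cost is
  a flat spot at saturation, acceptable at these gains.

Trigger magnitudes default to 1.0 for discrete events (win, lose, wave,
smile, personal-space invasion, the calm-down on entering the result
phase). Two exceptions:

* `cycle_repeat` scales as 0.2 × round index (capped at 1.0) — repetition
  dampens arousal more as the game wears on.
* `approach_go` is emitted once per tick while the machine sits in Ready,
  so its per-event magnitude is 0.05; a per-tick magnitude of 1.0 would
  pin arousal at the bound within a single tick rather than ramping it
  toward the "Go" moment. This keeps the intended anticipation ramp at
  the cost of tying the ramp slope to the tick rate.

Draws have no affect consequence.

## Face

V and A are quantized to five equal-width levels (bin edges at ±0.6 and
±0.2) and looked up in a 5×5 table of action-unit activations. The
shipped table (`data/au_map_synthetic.tsv`) is a synthetic stand-in
assembled from common FACS conventions — positive valence recruits
AU6+AU12, negative AU1+AU4+AU15, high arousal adds AU5, low arousal
AU43 — because the empirical mapping it stands in for is not
redistributable here. It is a plain TSV and fully replaceable; no test
asserts empirical values about it, only structural properties (neutral
centre, determinism, monotone modulation).

Personality modulation: intensities scale by `au_amount` (High 1.4,
Normal 1.0, Low 0.6), clip to [0, 1], and units below the category's
`filter_threshold` (Low 0.05, Normal 0.15, High 0.30) are dropped — the
"philtre" that makes introvert/stable faces flatter. The low-stability
categories additionally twitch: a Poisson process (2/min) perturbs one
random brow/mouth AU by +0.15 for 0.2 s. Rate and amplitude are
conventions chosen to be visible in a summary without dominating it; the
source material specifies presence/absence only.

## Gaze

Idle gaze is a two-state (mutual/avert) statistical model in the Eyes
Alive tradition. At each decision point the next episode is mutual with
probability `mutual_bias` (more-mutual 0.7, both 0.5, more-avert 0.3),
its duration uniform in the category's range (Short 0.5–1.5 s,
Med/Normal 1.5–3 s, Long 3–6 s, interpreted as (mutual, avert) ordered
pairs where the table prints two labels), and its direction drawn from
the category's direction set (uniform over the printed cell; centre is
forced during mutual gaze). After each episode the agent holds the
reached state for an exponential gap with mean 60/`avert_frequency`
(High 8, Normal 5, Low 3 decisions/min). The hold is what lets the
re-decision rate control how often avert episodes *start* independently
of the mutual/avert time split; episode durations alone would invert the
intended onset-frequency ordering for categories with short episodes.
Where the frequency cell prints two labels the first binds, consistent
with the onset-frequency orderings asserted in the tests.

Saccade amplitudes are drawn from an exponential with mean 8°, truncated
at 60° (a conventional stand-in for unpublished gaze statistics;
config-overridable). Eye–head coupling: requested amplitudes at or below
15° are executed by the eyes alone; beyond that the eyes saturate at 15°
and the head carries the remainder in the same direction, at the
category's head speed (Low 40, Normal 70, High 100 deg/s). The 15°
boundary itself is eyes-only. Reactive gaze tracks the user's angular
bearing through the same coupling; communicative gaze aims at fixed
targets (user 0°, GUI 35°, user's hand 20°).

Blinking is exponential with rate
λ = (11.6/60)·`blink_factor`·(1 + 0.5·max(0, A)) per second: an 11.6
blinks/min human baseline, a category factor (Low 0.8, Normal 1.0,
High 1.3), and acceleration under positive arousal only — negative
arousal does not slow blinking below baseline. Blinks are logged directly
rather than scheduled: they are too short to contend for actuators and
overlay any gaze command.

## Gesture and posture

Idle gestures arrive as a Poisson process at the category's `idle_rate`
(High 6, Normal 4, Low 2 events/min); each is a posture shift with the
category's printed probability (10/90/10/90/60 %) else a self-adaptor,
carrying a playback-speed multiplier (fast 1.6, normal 1.0, slow 0.6)
and the category's spaciousness flag (true for the two high-extraversion
categories). Lean is emitted once per session as a posture annotation
(backward for HELS/LELS, forward for HEHS/LEHS, none for Neutral).
Reactive waving answers a waving user at high priority, debounced to one
wave per wave duration (2 s). A fist emblem fires when affect enters the
very-angry corner (V < −0.7 and A > 0.7), logged together with whether
the concurrent face was frowning. Body twitches are Poisson (2/min) for
the low-stability categories only.

One source-table cell marks the LEHS category as twitching while the
companion face table and the accompanying text tie twitching to low
stability; the implementation follows the stability rule (twitches for
HELS and LELS only) and treats the cell as a typo. Setting
`gesture_options.table_literal_twitches: true` restores the literal cell.

## Attention and scheduling

Attention flags are scoped (gaze / body / both), raised by
attention-worthy events (a user wave pins both; the agent playing its
hand pins gaze; a personal-space invasion pins the body), and expire
after a 3 s hold unless renewed. While a flag is live, idle (low
priority) proposals in its scope are withheld; everything else passes.

The scheduler keeps three FIFO priority queues and resolves each tick:

* **high** — scheduled at the earliest onset free of other high
  commands, preempting (dropping, not pausing) any lower-priority
  command that conflicts there; never dropped itself;
* **mid** — shifted to the earliest conflict-free onset; dropped if the
  shift would exceed `defer_limit` (2 s);
* **low** — emitted if free, blended if it only conflicts with other low
  commands, dropped against anything higher.

Ties within a class break by requested onset, then insertion order.
Deferred commands occupy their scheduled interval like emitted ones.
Preemption drops rather than pauses because the design goal is to avoid
uncontrolled animation blending. The 8-way actuator taxonomy (eyes,
head, torso, arms, face halves, legs) is implementation plumbing — the
arbitration rules only need a notion of shared resources. The test suite
checks the scheduler against an independent brute-force oracle that
re-derives each onset by scanning a fine time grid.

## Synthetic user and session loop

The synthetic user stands ~2 m in front of the agent, takes short
walking bouts (2/min, 1.5 s), waves (1/min) and smiles (2/min) as
Poisson bouts, invades the agent's 1.2 m personal space occasionally
(0.5/min), and continuously offers a uniformly re-drawn RPS hand
(re-drawn every 2 s) that the game samples during its Hands window. It
emulates the *statistics* an actual sensing stack would deliver —
position, stillness, hand, wave/smile flags — not its failure modes: no
sensor noise, dropouts, misclassified gestures, or strategic play.
Passing tests therefore show that the architecture expresses and
recovers personality under clean input, not that it is robust to real
sensing.

Sessions default to 5 rounds in 120 s at a 0.1 s tick, matching a
roughly two-minute game pacing; state dwell times (Ready 2 s, Go 1 s,
Hands 1.5 s, Result 2 s) are conventions, as the source material gives
none. A user hand missing throughout the Hands window is logged as a
missed round with no outcome event. "Standing still" means the stream's
`moving` flag is false; the synthetic generator derives it from walking
bouts (threshold convention: speed below 0.1 m/s over 0.5 s).

Determinism: one master seed is split (`numpy` `SeedSequence.spawn`)
into named per-module streams (user, game, affect, gaze, blink, face,
gesture), so identical configs reproduce byte-identical logs and
module-level tests draw the same numbers as full sessions. Request ids
are renumbered in submission order at session end to keep serialized
audits reproducible across processes.

## Summaries and personality recovery

A session reduces to eight statistics: blink rate, mutual-gaze time
fraction, posture-shift fraction, idle-gesture rate, twitch count, mean
valence, mean arousal, mean expressed AU intensity. These mirror the
cues observers use when attributing extraversion and stability to
animated characters. Recovery is nearest-centroid in standardized
summary space: centroids are means of 10 reference runs per category at
fixed seeds (shipped as `data/centroids.json`, regenerable with
`personasim build-centroids`), standardization uses the pooled
per-feature mean/std of those runs, and near-zero-variance features are
excluded with a warning. The acceptance threshold for 5-way recovery of
held-out runs is 0.8 against a 0.2 chance level — a repository target
for "the behaviour conveys the category", not an empirical claim from
human raters.

## Known limitations

* Behaviour ends at the command level; expressivity (speed, spaciousness,
  lean) is attributes, not kinematics, and "blended" is an outcome label,
  not animation math.
* The AU table is synthetic; absolute facial intensities are
  conventions, though all cross-category orderings are table-driven.
* Affect uses valence and arousal only — no dominance dimension, no
  slower mood layer.
* The approach-to-"Go" arousal ramp depends on tick rate (see above).
* Five discrete personality settings; continuous traits are snapped to a
  category rather than interpolated.
* Human-rater phenomena (perceived personality, likeability) are out of
  scope; the machine-recovery criterion is a proxy with different
  failure modes.
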