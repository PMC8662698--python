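# personasim

A desk-scale simulator of a virtual agent whose **personality** shapes its
**nonverbal behaviour**. Personality is a point on the Extraversion ×
Emotional-Stability plane, discretized into five categories (the four
corners HELS, HEHS, LELS, LEHS plus a Neutral midpoint). The category
parameterizes two coupled layers:

1. **Emotion regulation** — a bounded valence–arousal state
   (V, A) ∈ [−1, 1]² on the circumplex plane, driven by interaction
   events ("triggers") and relaxing toward a personality-dependent
   baseline:

   ```
   V ← clip( V − γ (V − V₀) dt  +  Σᵢ sᵢ g(sᵢ) w(nᵢ) mᵢ  +  σ √dt ξ )
   ```

   where γ is the decay rate, g(±) the positive/negative reaction gains,
   w(n) the Maslow need weight of the trigger (safety > belonging >
   self-esteem), m the trigger magnitude, and σ the lability (spontaneous
   valence fluctuation). Arousal follows the same form with its own gain
   and no lability term.

2. **Behaviour generation and arbitration** — the affect state and the
   category's parameter tables modulate four controllers:
   * **face**: (V, A) quantized to 5×5 levels → FACS action units, scaled,
     threshold-filtered ("philtre") and optionally twitching;
   * **gaze**: two-state mutual/avert idle saccades with per-category bias,
     durations, directions and head speed; eye rotations cap at 15° with the
     excess carried by a same-direction head movement; blinking at a
     baseline of 11.6/min, scaled by category and accelerated by arousal;
   * **gesture/posture**: idle posture shifts vs self-adaptors at the
     category's printed split (e.g. 90%/10% for HEHS), plus waves, RPS hand
     gestures, a fist emblem when very angry, and body twitches for the
     low-stability categories;
   * **executive**: scoped attention flags suppress idle behaviour during
     deliberate acts, and a three-level priority scheduler resolves actuator
     conflicts (high preempts, mid defers up to a limit, low blends or drops).

   The interaction itself is a rock-paper-scissors game run by a
   Ready → Go → Hands → Result finite state machine against a synthetic
   (or scripted) user.

The output of a session is a `BehaviourLog` — the affect trace plus every
scheduled command — which can be reduced to a behaviour summary
(blink rate, mutual-gaze fraction, idle-gesture composition, twitch count,
affect means, expressed facial intensity) and classified back to a
personality category by nearest-centroid matching. That closes the loop:
the intended personality is recoverable from behaviour alone.

## Worked example

Simulate a high-extraversion/high-stability session of five game rounds
and print its behaviour summary:

```
$ personasim simulate --personality HEHS --seed 3
{
 "blink_rate": 6.5,
 "mutual_gaze_fraction": 0.6505964604900564,
 "posture_shift_fraction": 1.0,
 "idle_gesture_rate": 1.5,
 "twitch_count": 0,
 "mean_valence": 0.5939216175278513,
 "mean_arousal": -0.35549662879453325,
 "mean_au_intensity": 0.5911791666666666
}
```

Read against the HEHS parameter tables: blinking is slow (low blink
factor), idle gaze is mostly mutual, every idle gesture in this short
session was a posture shift (the HEHS split is 90/10), there are no
twitches (high stability), valence settles clearly positive (positive
baseline and a strong positive-reaction gain), arousal below its slightly
negative baseline, and facial expression is intense (high action-unit
scaling). Classifying a fresh session recovers the intended category from
the behaviour summary:

```
$ personasim classify --personality LELS --seed 9
{"intended": "LELS", "recovered": "LELS"}
```

`personasim simulate --out-bml out.xml --out-log events.jsonl
--out-trace trace.csv` additionally writes the scheduled commands as a
Behavior Markup Language subset, the game events as JSONL and the affect
trace as CSV.

## Layout

```
src/personasim/
  core.py        personality categories, parameter tables, config resolution
  emotion.py     triggers and valence-arousal integration
  fsm.py         rock-paper-scissors turn-taking state machine
  face.py        action-unit mapping and facial modulation
  gaze.py        idle/reactive/communicative gaze and blinking
  gesture.py     idle/reactive/communicative gestures and postures
  executive.py   attention flags and the priority scheduler
  simulation.py  synthetic users, the session loop, summaries, recovery
  bml.py         BML-subset serialization
  cli.py         the `personasim` command
  data/          default config, synthetic AU table, reference centroids
docs/methods.md  model description, defaults, and design rationale
```
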