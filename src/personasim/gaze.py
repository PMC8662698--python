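"""Gaze generation: idle mutual/avert saccades, user tracking, blinks.

Idle gaze follows a two-state statistical model in the style of the
"Eyes Alive" family: episodes of *mutual* gaze (at the user) alternate
with *avert* episodes (looking away), with per-personality bias, episode
durations, directions and re-decision rate.  Saccade amplitudes beyond
15 degrees recruit a same-direction head rotation carrying the excess,
so the eyes alone never rotate more than 15 degrees.  Blinking is a
Poisson process at a human baseline of 11.6 blinks/min, scaled by a
personality factor and accelerated by positive arousal.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import GazeParams

__all__ = [
    "GazeEvent",
    "saccade_head_coupling",
    "idle_gaze_step",
    "idle_gaze_stream",
    "blink_interval",
    "reactive_gaze",
    "communicative_gaze",
]

EYE_LIMIT_DEG = 15.0
SACCADE_MEAN_DEG = 8.0
SACCADE_MAX_DEG = 60.0
BLINK_BASE_PER_MIN = 11.6
AROUSAL_BLINK_GAIN = 0.5

#: Bearing (degrees off straight-ahead) of the fixed communicative targets.
TARGET_BEARINGS = {"user": 0.0, "gui": 35.0, "user_hand": 20.0}
TARGET_DIRECTIONS = {"user": "C", "gui": "R", "user_hand": "D"}


@dataclass(frozen=True)
class GazeEvent:
    time: float
    kind: str           # idle_saccade | reactive_track | communicative | blink
    gaze_state: str     # mutual | avert
    direction: str      # U | D | L | R | C
    eye_amplitude: float
    head_rotation: float
    head_speed: float
    duration: float

    def __post_init__(self) -> None:
        if self.eye_amplitude > EYE_LIMIT_DEG + 1e-9:
            raise ValueError("eye amplitude exceeds the saccade limit")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def saccade_head_coupling(requested_amplitude: float) -> tuple[float, float]:
    """Split a requested gaze amplitude into (eye, head) components.

    Saccades up to 15 degrees are executed by the eyes alone; anything
    beyond recruits a head rotation in the same direction for the excess.
    """
    if requested_amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if requested_amplitude <= EYE_LIMIT_DEG:
        return (requested_amplitude, 0.0)
    return (EYE_LIMIT_DEG, requested_amplitude - EYE_LIMIT_DEG)


def _sample_amplitude(rng: np.random.Generator,
                      mean: float = SACCADE_MEAN_DEG,
                      upper: float = SACCADE_MAX_DEG) -> float:
    # exponential truncated at `upper`, via inverse CDF
    u = rng.random()
    return -mean * math.log1p(-u * (1.0 - math.exp(-upper / mean)))


def idle_gaze_step(
    current: str,
    params: GazeParams,
    rng: np.random.Generator,
    time: float = 0.0,
) -> GazeEvent:
    """Draw the next idle gaze episode (mutual or avert)."""
    mutual = rng.random() < params.mutual_bias
    state = "mutual" if mutual else "avert"
    lo, hi = params.mutual_duration_range if mutual else params.avert_duration_range
    duration = rng.uniform(lo, hi)
    if mutual:
        direction = "C"
    else:
        dirs = list(params.direction_weights)
        weights = np.array([params.direction_weights[d] for d in dirs])
        direction = str(rng.choice(dirs, p=weights / weights.sum()))
    eye, head = saccade_head_coupling(_sample_amplitude(rng))
    return GazeEvent(
        time=time, kind="idle_saccade", gaze_state=state, direction=direction,
        eye_amplitude=eye, head_rotation=head, head_speed=params.head_speed,
        duration=duration,
    )


def idle_gaze_stream(
    params: GazeParams,
    duration: float,
    rng: np.random.Generator,
    start: float = 0.0,
) -> list[GazeEvent]:
    """Generate a timeline of idle gaze episodes over ``duration`` seconds.

    After each episode the agent holds the reached state for an
    exponential gap with mean ``60 / avert_frequency`` before redeciding,
    so the per-category re-decision rate controls how often avert
    episodes are initiated.  The state between consecutive events is the
    earlier event's state.
    """
    events: list[GazeEvent] = []
    t = start
    state = "mutual"
    while t < start + duration:
        ev = idle_gaze_step(state, params, rng, time=t)
        events.append(ev)
        state = ev.gaze_state
        hold = rng.exponential(60.0 / params.avert_frequency)
        t += ev.duration + hold
    return events


def mutual_gaze_fraction(events: list[GazeEvent], total: float | None = None) -> float:
    """Fraction of time spent in mutual gaze over an idle event timeline."""
    if not events:
        raise ValueError("empty gaze timeline")
    end = total if total is not None else events[-1].time + events[-1].duration
    acc = 0.0
    for ev, nxt in zip(events, events[1:] + [None]):
        span = (nxt.time if nxt is not None else end) - ev.time
        if ev.gaze_state == "mutual":
            acc += max(0.0, span)
    return acc / (end - events[0].time)


def blink_rate(arousal: float, params: GazeParams,
               base_per_min: float = BLINK_BASE_PER_MIN,
               arousal_gain: float = AROUSAL_BLINK_GAIN) -> float:
    """Instantaneous blink rate in blinks/second."""
    if not (-1.0 <= arousal <= 1.0):
        raise ValueError("arousal must lie in [-1, 1]")
    return (base_per_min / 60.0) * params.blink_factor * (1.0 + arousal_gain * max(0.0, arousal))


def blink_interval(
    arousal: float,
    params: GazeParams,
    rng: np.random.Generator,
    base_per_min: float = BLINK_BASE_PER_MIN,
    arousal_gain: float = AROUSAL_BLINK_GAIN,
) -> float:
    """Sample the next inter-blink interval (exponential, seconds)."""
    lam = blink_rate(arousal, params, base_per_min, arousal_gain)
    return float(rng.exponential(1.0 / lam))


def blink_event(time: float, params: GazeParams) -> GazeEvent:
    return GazeEvent(time=time, kind="blink", gaze_state="mutual", direction="C",
                     eye_amplitude=0.0, head_rotation=0.0,
                     head_speed=params.head_speed, duration=0.15)


def _bearing_event(kind: str, bearing: float, direction: str, time: float,
                   head_speed: float, duration: float = 1.0) -> GazeEvent:
    eye, head = saccade_head_coupling(abs(bearing))
    return GazeEvent(time=time, kind=kind, gaze_state="mutual", direction=direction,
                     eye_amplitude=eye, head_rotation=head, head_speed=head_speed,
                     duration=duration)


def reactive_gaze(user_position: tuple[float, float], time: float = 0.0,
                  head_speed: float = 70.0) -> GazeEvent:
    """Track the user: gaze along the angular bearing of their position.

    Position is (x, y) in the agent-centred ground plane, y pointing
    straight ahead, x to the agent's right.
    """
    x, y = user_position
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("user position must be finite")
    bearing = math.degrees(math.atan2(x, max(y, 1e-9)))
    if abs(bearing) < 2.0:
        direction = "C"
    else:
        direction = "R" if bearing > 0 else "L"
    return _bearing_event("reactive_track", bearing, direction, time, head_speed)


def communicative_gaze(target: str, time: float = 0.0,
                       head_speed: float = 70.0,
                       bearings: dict | None = None) -> GazeEvent:
    """Gaze at a fixed interaction target (the user, the GUI, the user's hand)."""
    table = bearings if bearings is not None else TARGET_BEARINGS
    if target not in table:
        raise ValueError(f"unknown gaze target {target!r}")
    return _bearing_event(
        "communicative", table[target], TARGET_DIRECTIONS.get(target, "C"),
        time, head_speed,
    )
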