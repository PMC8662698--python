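"""Gesture and posture generation with personality expressivity.

Idle behaviour alternates between whole-body posture shifts and
self-adaptors (self-touch such as scratching), mixed per personality:
the stable categories mostly shift posture, the unstable ones mostly
self-adapt.  On top sit reactive acts (waving back at a waving user),
communicative acts (rock/paper/scissors hands, pointing), emotional
emblems (a fist when very angry) and, for the low-stability categories,
Poisson-timed body twitches.  Expressivity is carried as attributes —
playback-speed multiplier, spatial extent, lean — rather than joint
trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GestureParams
from .emotion import AffectState

__all__ = [
    "GestureEvent",
    "GestureController",
    "select_idle_gesture",
    "emblem_for_emotion",
    "reactive_gesture",
    "communicative_gesture",
    "body_twitch_stream",
]

IDLE_KINDS = frozenset({"posture_shift", "self_adaptor", "body_twitch", "lean_set"})
HAND_KINDS = {"rock": "hand_rock", "paper": "hand_paper", "scissors": "hand_scissors"}

EMBLEM_VALENCE_MAX = -0.7
EMBLEM_AROUSAL_MIN = 0.7
BODY_TWITCH_RATE_PER_MIN = 2.0
WAVE_DURATION_S = 2.0

_BASE_DURATION = {"posture_shift": 2.5, "self_adaptor": 2.0, "wave": WAVE_DURATION_S,
                  "hand_rock": 1.5, "hand_paper": 1.5, "hand_scissors": 1.5,
                  "point": 1.5, "emblem_fist": 1.5, "body_twitch": 0.3, "lean_set": 1.0}

_ACTUATORS = {"posture_shift": frozenset({"torso", "legs"}),
              "self_adaptor": frozenset({"right_arm"}),
              "wave": frozenset({"right_arm"}),
              "hand_rock": frozenset({"right_arm"}),
              "hand_paper": frozenset({"right_arm"}),
              "hand_scissors": frozenset({"right_arm"}),
              "point": frozenset({"right_arm"}),
              "emblem_fist": frozenset({"right_arm"}),
              "body_twitch": frozenset({"torso"}),
              "lean_set": frozenset({"torso"})}


@dataclass(frozen=True)
class GestureEvent:
    time: float
    category: str          # idle | reactive | communicative
    kind: str
    speed_multiplier: float
    spacious: bool
    actuators: frozenset
    duration: float

    def __post_init__(self) -> None:
        if self.category == "idle" and self.kind not in IDLE_KINDS:
            raise ValueError(f"{self.kind!r} is not an idle gesture kind")
        if self.speed_multiplier <= 0 or self.duration <= 0:
            raise ValueError("speed multiplier and duration must be positive")


def _event(kind: str, category: str, time: float, speed: float = 1.0,
           spacious: bool = False) -> GestureEvent:
    return GestureEvent(
        time=time, category=category, kind=kind, speed_multiplier=speed,
        spacious=spacious, actuators=_ACTUATORS[kind],
        duration=_BASE_DURATION[kind] / speed,
    )


def select_idle_gesture(
    params: GestureParams,
    affect: AffectState,
    rng: np.random.Generator,
    time: float = 0.0,
) -> GestureEvent:
    """Draw one idle gesture: posture shift vs self-adaptor per the category mix."""
    shift = rng.random() < params.posture_shift_prob
    kind = "posture_shift" if shift else "self_adaptor"
    speed = params.posture_shift_speed if shift else params.self_adaptor_speed
    return _event(kind, "idle", time, speed, params.spacious)


def emblem_for_emotion(
    affect: AffectState,
    valence_max: float = EMBLEM_VALENCE_MAX,
    arousal_min: float = EMBLEM_AROUSAL_MIN,
    time: float = 0.0,
) -> GestureEvent | None:
    """A fist emblem when affect sits in the very-angry corner (low valence,
    high arousal); None elsewhere."""
    if affect.valence < valence_max and affect.arousal > arousal_min:
        return _event("emblem_fist", "communicative", time)
    return None


def reactive_gesture(waving: bool, time: float = 0.0) -> GestureEvent | None:
    """Wave back at a waving user (stateless; debouncing is the controller's job)."""
    if waving:
        return _event("wave", "reactive", time)
    return None


def communicative_gesture(request: str, params: GestureParams | None = None,
                          time: float = 0.0) -> GestureEvent:
    """Build a communicative act: an RPS hand or a pointing gesture."""
    if request in HAND_KINDS:
        kind = HAND_KINDS[request]
    elif request == "point":
        kind = "point"
    else:
        raise ValueError(f"unknown communicative gesture request {request!r}")
    spacious = params.spacious if params is not None else False
    return _event(kind, "communicative", time, spacious=spacious)


def body_twitch_stream(
    params: GestureParams,
    rng: np.random.Generator,
    duration: float,
    rate_per_min: float = BODY_TWITCH_RATE_PER_MIN,
    start: float = 0.0,
) -> list[GestureEvent]:
    """Poisson-timed involuntary body twitches; empty unless the category twitches."""
    if not params.twitch_enabled or duration <= 0:
        return []
    events = []
    t = start + rng.exponential(60.0 / rate_per_min)
    while t < start + duration:
        events.append(_event("body_twitch", "idle", t, speed=1.6))
        t += rng.exponential(60.0 / rate_per_min)
    return events


def lean_event(params: GestureParams, time: float = 0.0) -> GestureEvent | None:
    """Session-opening posture annotation: the category's habitual lean."""
    if params.lean == "none":
        return None
    return _event("lean_set", "idle", time, spacious=params.spacious)


class GestureController:
    """Stateful wrapper adding wave debouncing and idle-rate timing."""

    def __init__(self, params: GestureParams, rng: np.random.Generator,
                 wave_duration: float = WAVE_DURATION_S):
        self.params = params
        self.rng = rng
        self.wave_duration = wave_duration
        self._wave_busy_until = -np.inf
        self._next_idle = rng.exponential(60.0 / params.idle_rate)

    def maybe_wave(self, waving: bool, clock: float) -> GestureEvent | None:
        """Wave back, at most once per wave duration (debounced)."""
        if not waving or clock < self._wave_busy_until:
            return None
        event = reactive_gesture(True, time=clock)
        self._wave_busy_until = clock + self.wave_duration
        return event

    def maybe_idle(self, affect: AffectState, clock: float) -> GestureEvent | None:
        """Emit an idle gesture when the Poisson idle timer fires."""
        if clock < self._next_idle:
            return None
        self._next_idle = clock + self.rng.exponential(60.0 / self.params.idle_rate)
        return select_idle_gesture(self.params, affect, self.rng, time=clock)
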