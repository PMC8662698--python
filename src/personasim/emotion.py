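"""Continuous valence-arousal regulation.

The agent's affective state is a bounded point (valence, arousal) in
[-1, 1]^2 on the circumplex plane.  Interaction and game events become
*triggers* — impulses on one of the two channels, weighted by the need
level they touch (safety > belonging > esteem, after Maslow's hierarchy).
Between impulses the state relaxes exponentially toward a
personality-dependent baseline, and a lability term injects spontaneous
zero-mean valence fluctuation for the emotionally less stable categories.

Update rule (explicit Euler at step ``dt``), applied to valence V:

    V <- clip(V - dt * decay_rate * (V - baseline_V)
                + sum_i sign_i * gain(sign_i) * w(need_i) * magnitude_i
                + lability * sqrt(dt) * xi),     xi ~ N(0, 1)

with ``gain(+1) = gain_pos`` and ``gain(-1) = gain_neg``; arousal uses
``arousal_gain`` for both signs and carries no lability term.  Clipping
(rather than squashing) enforces the bounds so the interior dynamics stay
linear.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import AffectDynamicsParams

__all__ = [
    "NeedLevel",
    "Trigger",
    "AffectState",
    "AffectTrace",
    "trigger_weight",
    "rps_event_to_triggers",
    "step_affect",
    "affect_attractor",
]

DEFAULT_TRIGGER_WEIGHTS = {"safety": 1.0, "belonging": 0.6, "esteem": 0.3}

GAME_EVENTS = frozenset({
    "agent_win", "agent_lose", "draw", "approach_go", "enter_wait",
    "cycle_repeat", "user_wave", "user_smile", "space_invasion",
})


class NeedLevel(str, enum.Enum):
    SAFETY = "safety"
    BELONGING = "belonging"
    ESTEEM = "esteem"


@dataclass(frozen=True)
class AffectState:
    valence: float
    arousal: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.valence <= 1.0 and -1.0 <= self.arousal <= 1.0):
            raise ValueError(f"affect state out of bounds: {self}")


@dataclass(frozen=True)
class Trigger:
    """A timestamped affect impulse on one channel with a need-level weight."""

    time: float
    need_level: NeedLevel
    channel: str            # "valence" | "arousal"
    sign: int               # +1 | -1
    magnitude: float

    def __post_init__(self) -> None:
        if self.channel not in ("valence", "arousal"):
            raise ValueError(f"invalid channel {self.channel!r}")
        if self.sign not in (+1, -1):
            raise ValueError(f"sign must be +1 or -1, got {self.sign}")
        if not (0.0 < self.magnitude <= 1.0):
            raise ValueError(f"magnitude must lie in (0, 1], got {self.magnitude}")


def trigger_weight(need_level: NeedLevel | str, weights: dict | None = None) -> float:
    """Weight of a need level; safety outranks belonging outranks esteem."""
    level = NeedLevel(need_level)
    table = weights if weights is not None else DEFAULT_TRIGGER_WEIGHTS
    try:
        return float(table[level.value])
    except KeyError as exc:
        raise ValueError(f"no weight configured for need level {level}") from exc


def rps_event_to_triggers(
    event: str,
    time: float = 0.0,
    round_index: int = 0,
    magnitudes: dict | None = None,
) -> list[Trigger]:
    """Translate an interaction/game event into affect triggers.

    Game outcomes touch self-esteem; positive user feedback (waves,
    smiles) touches belonging; a personal-space invasion touches safety
    and hence carries the heaviest weight.  Approaching the "Go" moment
    excites, settling into "Wait" calms, and each repeated game cycle
    dampens arousal a little more (magnitude grows with ``round_index``,
    capped at 1).
    """
    if event not in GAME_EVENTS:
        raise ValueError(f"unknown game event {event!r}")
    mag = dict(DEFAULT_MAGNITUDES)
    if magnitudes:
        mag.update(magnitudes)

    def t(channel, sign, need, magnitude=None):
        return Trigger(time, NeedLevel(need), channel, sign,
                       magnitude if magnitude is not None else mag[event])

    if event == "agent_win":
        return [t("valence", +1, "esteem")]
    if event == "agent_lose":
        return [t("valence", -1, "esteem")]
    if event in ("user_wave", "user_smile"):
        return [t("valence", +1, "belonging")]
    if event == "approach_go":
        return [t("arousal", +1, "esteem")]
    if event == "enter_wait":
        return [t("arousal", -1, "esteem")]
    if event == "cycle_repeat":
        m = min(1.0, mag["cycle_repeat_per_round"] * max(1, round_index))
        return [t("arousal", -1, "esteem", m)]
    if event == "space_invasion":
        return [t("arousal", +1, "safety")]
    return []  # draw: no stated affect consequence


DEFAULT_MAGNITUDES = {
    "agent_win": 1.0,
    "agent_lose": 1.0,
    "user_wave": 1.0,
    "user_smile": 1.0,
    "space_invasion": 1.0,
    "enter_wait": 1.0,
    "approach_go": 0.05,
    "cycle_repeat_per_round": 0.2,
}


def step_affect(
    state: AffectState,
    triggers: list[Trigger],
    params: AffectDynamicsParams,
    dt: float,
    rng: np.random.Generator | None = None,
    weights: dict | None = None,
) -> AffectState:
    """Advance the affect state by one Euler step of length ``dt`` seconds."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    dv = -dt * params.decay_rate * (state.valence - params.baseline_valence)
    da = -dt * params.decay_rate * (state.arousal - params.baseline_arousal)
    for trig in triggers:
        w = trigger_weight(trig.need_level, weights)
        if trig.channel == "valence":
            gain = params.gain_pos if trig.sign > 0 else params.gain_neg
            dv += trig.sign * gain * w * trig.magnitude
        else:
            da += trig.sign * params.arousal_gain * w * trig.magnitude
    if params.lability > 0:
        if rng is None:
            raise ValueError("lability > 0 requires a random generator")
        dv += params.lability * math.sqrt(dt) * rng.standard_normal()
    return AffectState(
        valence=float(np.clip(state.valence + dv, -1.0, 1.0)),
        arousal=float(np.clip(state.arousal + da, -1.0, 1.0)),
        time=state.time + dt,
    )


class AffectTrace:
    """Uniformly sampled record of an affect trajectory."""

    def __init__(self, dt: float):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.dt = dt
        self.times: list[float] = []
        self.valence: list[float] = []
        self.arousal: list[float] = []

    def append(self, state: AffectState) -> None:
        if self.times and state.time < self.times[-1]:
            raise ValueError("trace times must be non-decreasing")
        self.times.append(state.time)
        self.valence.append(state.valence)
        self.arousal.append(state.arousal)

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "valence": self.valence, "arousal": self.arousal}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AffectTrace":
        df = pd.read_csv(path)
        dt = float(df["time"].diff().dropna().median()) if len(df) > 1 else 1.0
        trace = cls(dt)
        for row in df.itertuples(index=False):
            trace.append(AffectState(row.valence, row.arousal, row.time))
        return trace


def affect_attractor(trace: AffectTrace, burn_in: float = 0.0) -> tuple[float, float]:
    """Mean (valence, arousal) of the post-burn-in trajectory.

    Long-run averages summarize where a personality's affect dynamics
    settle on the circumplex plane — its attractor region.
    """
    times = np.asarray(trace.times)
    keep = times >= burn_in
    if not keep.any():
        raise ValueError("no samples after burn-in")
    return (
        float(np.mean(np.asarray(trace.valence)[keep])),
        float(np.mean(np.asarray(trace.arousal)[keep])),
    )
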