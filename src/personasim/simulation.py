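"""Session orchestration: synthetic users, the tick loop, summaries, recovery.

``run_session`` wires every module together at a fixed tick: the game
FSM produces events, events become affect triggers, the affect state is
integrated, the gaze/face/gesture controllers propose behaviour, the
attention controller gates idle proposals, and the scheduler resolves
actuator conflicts.  The result is a ``BehaviourLog`` — the affect trace
plus every emitted command — from which ``summarize`` computes the
behavioural statistics that carry the personality signal, and
``classify_personality`` recovers the intended category by
nearest-centroid matching against reference runs.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import face as face_mod
from . import gaze as gaze_mod
from .core import (
    PersonalityCategory, PersonalityProfile, load_config, load_parameters,
)
from .emotion import (
    AffectState, AffectTrace, GAME_EVENTS, affect_attractor, rps_event_to_triggers,
    step_affect, Trigger, NeedLevel,
)
from .executive import (
    AttentionController, Modality, Priority, ScheduledCommand, Scheduler,
    attention_gate,
)
from .fsm import (
    GameState, RPSInteraction, UserInput, gaze_request, gesture_request,
)
from .gesture import GestureController, body_twitch_stream, emblem_for_emotion, lean_event

__all__ = [
    "SessionConfig",
    "BehaviourLog",
    "BehaviourSummary",
    "SUMMARY_FEATURES",
    "synth_user_stream",
    "run_session",
    "summarize",
    "build_centroids",
    "classify_personality",
]

SUMMARY_FEATURES = (
    "blink_rate",
    "mutual_gaze_fraction",
    "posture_shift_fraction",
    "idle_gesture_rate",
    "twitch_count",
    "mean_valence",
    "mean_arousal",
    "mean_au_intensity",
)

DEFAULT_USER_PROFILE = {
    "wave_rate_per_min": 1.0,
    "smile_rate_per_min": 2.0,
    "invasion_rate_per_min": 0.5,
    "move_rate_per_min": 2.0,
    "move_duration_s": 1.5,
    "wave_duration_s": 1.5,
    "smile_duration_s": 2.0,
    "invasion_duration_s": 2.0,
    "hand_redraw_s": 2.0,
    "walk_speed": 0.4,
    "home": (0.0, 2.0),
    "personal_space_radius": 1.2,
}


@dataclass(frozen=True)
class SessionConfig:
    personality: PersonalityCategory | PersonalityProfile | str = PersonalityCategory.NEUTRAL
    rounds: int = 5
    duration: float = 120.0
    tick: float = 0.1
    seed: int = 0
    scenario: str = "rps"  # rps | idle_only
    config_overrides: dict | None = None

    def __post_init__(self) -> None:
        if self.tick <= 0:
            raise ValueError("tick must be positive")
        if self.scenario not in ("rps", "idle_only"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.rounds <= 0:
            raise ValueError("rounds must be positive")
        min_round = sum((2.0, 1.0, 1.5, 2.0))
        if self.scenario == "rps" and self.duration < self.rounds * min_round:
            raise ValueError("duration too short for the requested number of rounds")

    @property
    def category(self) -> PersonalityCategory:
        if isinstance(self.personality, PersonalityProfile):
            return self.personality.category
        return PersonalityCategory(self.personality)


@dataclass
class BehaviourLog:
    config: SessionConfig
    trace: AffectTrace
    commands: list[ScheduledCommand] = field(default_factory=list)
    blinks: list = field(default_factory=list)
    events: list[dict] = field(default_factory=list)
    audit: list[ScheduledCommand] = field(default_factory=list)
    face_twitch_count: int = 0
    au_intensity_trace: list[float] = field(default_factory=list)

    def events_to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for ev in self.events:
                fh.write(json.dumps(ev) + "\n")

    def audit_to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for cmd in self.audit:
                fh.write(json.dumps({
                    "id": cmd.request.id,
                    "modality": cmd.request.modality.value,
                    "priority": int(cmd.request.priority),
                    "requested_onset": round(cmd.request.requested_onset, 4),
                    "scheduled_onset": round(cmd.scheduled_onset, 4),
                    "outcome": cmd.outcome,
                }) + "\n")


@dataclass(frozen=True)
class BehaviourSummary:
    blink_rate: float            # blinks / min
    mutual_gaze_fraction: float
    posture_shift_fraction: float
    idle_gesture_rate: float     # idle gestures / min
    twitch_count: int
    mean_valence: float
    mean_arousal: float
    mean_au_intensity: float

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in SUMMARY_FEATURES], dtype=float)


def synth_user_stream(
    seed: int,
    duration: float,
    profile: dict | None = None,
    tick: float = 0.1,
) -> pd.DataFrame:
    """Generate a synthetic user timeline at tick resolution.

    The user mostly stands still near a home position two metres in
    front of the agent, takes short walking bouts (occasionally invading
    the agent's personal space), waves and smiles as Poisson events, and
    continuously offers a uniformly re-drawn RPS hand that the game
    samples during its Hands window.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    prof = dict(DEFAULT_USER_PROFILE, **(profile or {}))
    rng = np.random.default_rng(seed)
    n = int(round(duration / tick))
    times = np.arange(n) * tick

    def bouts(rate_per_min: float, bout_len: float) -> np.ndarray:
        """Boolean mask over ticks flagged by Poisson-started bouts."""
        mask = np.zeros(n, dtype=bool)
        if rate_per_min <= 0:
            return mask
        t = rng.exponential(60.0 / rate_per_min)
        while t < duration:
            i0 = int(t / tick)
            mask[i0:i0 + max(1, int(bout_len / tick))] = True
            t += rng.exponential(60.0 / rate_per_min)
        return mask

    waving = bouts(prof["wave_rate_per_min"], prof["wave_duration_s"])
    smiling = bouts(prof["smile_rate_per_min"], prof["smile_duration_s"])
    moving = bouts(prof["move_rate_per_min"], prof["move_duration_s"])
    invading = bouts(prof["invasion_rate_per_min"], prof["invasion_duration_s"])
    moving |= invading  # an invasion is a walking bout toward the agent

    hx, hy = prof["home"]
    x, y = hx, hy
    xs, ys = np.empty(n), np.empty(n)
    radius = prof["personal_space_radius"]
    for i in range(n):
        if invading[i]:
            # walk toward the agent until well inside the personal space
            target = (0.0, 0.6 * radius)
        elif moving[i]:
            target = (hx + rng.normal(0, 0.5), hy + rng.normal(0, 0.5))
        else:
            target = (hx, hy)
        dx, dy = target[0] - x, target[1] - y
        dist = float(np.hypot(dx, dy))
        step = prof["walk_speed"] * tick
        if moving[i] and dist > 1e-6:
            frac = min(1.0, step / dist)
            x, y = x + frac * dx, y + frac * dy
        if not invading[i]:
            y = max(y, radius * 1.05)  # only invasions enter the personal space
        xs[i], ys[i] = x, y

    redraw = max(1, int(prof["hand_redraw_s"] / tick))
    hand_draws = rng.integers(3, size=n // redraw + 1)
    hands = np.array(["rock", "paper", "scissors"])[hand_draws[np.arange(n) // redraw]]

    return pd.DataFrame({
        "time": times, "hand": hands, "x": xs, "y": ys,
        "moving": moving, "waving": waving, "smiling": smiling,
    })


def load_user_stream(path) -> pd.DataFrame:
    """Read a scripted user timeline from CSV (time, hand, x, y, moving, waving, smiling)."""
    df = pd.read_csv(path)
    required = {"time", "hand", "x", "y", "moving", "waving", "smiling"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"user stream is missing columns {sorted(missing)}")
    return df


def _input_at(stream: pd.DataFrame, i: int) -> UserInput:
    row = stream.iloc[min(i, len(stream) - 1)]
    return UserInput(
        time=float(row["time"]), hand=str(row["hand"]),
        position=(float(row["x"]), float(row["y"])),
        moving=bool(row["moving"]), waving=bool(row["waving"]),
        smiling=bool(row["smiling"]),
    )


def run_session(config: SessionConfig, user_stream: pd.DataFrame | None = None) -> BehaviourLog:
    """Simulate one full session and return its behaviour log."""
    model_cfg = load_config(overrides=config.config_overrides)
    category = config.category
    affect_params, face_params, gaze_params, gesture_params = load_parameters(
        category, model_cfg
    )
    eo = model_cfg["emotion_options"]
    go = model_cfg["gaze_options"]
    fo = model_cfg["face_options"]
    geo = model_cfg["gesture_options"]
    xo = model_cfg["executive_options"]
    so = model_cfg["simulation_options"]

    # one master seed, split into named per-module streams
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_user, rng_fsm, rng_affect, rng_gaze, rng_blink, rng_face, rng_gesture = (
        np.random.default_rng(s) for s in streams
    )

    if user_stream is None:
        user_seed = int(streams[0].generate_state(1)[0] % (2**31))
        user_stream = synth_user_stream(user_seed, config.duration, tick=config.tick)

    dt = config.tick
    n = int(round(config.duration / dt))
    au_map = face_mod.load_au_map()

    machine = (
        RPSInteraction(
            rng_fsm, rounds=config.rounds, dwell=model_cfg["fsm_options"]["dwell"],
            gesture_params=gesture_params, head_speed=gaze_params.head_speed,
        )
        if config.scenario == "rps" else None
    )
    attention = AttentionController(hold=xo["attention_hold"])
    scheduler = Scheduler(defer_limit=xo["defer_limit"])
    gestures = GestureController(gesture_params, rng_gesture,
                                 wave_duration=geo["wave_duration_s"])
    twitcher = face_mod.FaceTwitcher(
        face_params, rng_face, rate_per_min=fo["twitch_rate_per_min"],
        amplitude=fo["twitch_amplitude"], duration=fo["twitch_duration_s"],
    )

    state = AffectState(affect_params.baseline_valence, affect_params.baseline_arousal, 0.0)
    trace = AffectTrace(dt)
    trace.append(state)
    log = BehaviourLog(config=config, trace=trace)

    body_twitches = body_twitch_stream(
        gesture_params, rng_gesture, config.duration,
        rate_per_min=geo["body_twitch_rate_per_min"],
    )
    twitch_cursor = 0

    lean = lean_event(gesture_params, time=0.0)
    if lean is not None:
        scheduler.submit(gesture_request(lean, Priority.LOW))

    next_gaze_decision = 0.0
    next_blink = float(gaze_mod.blink_interval(
        state.arousal, gaze_params, rng_blink,
        base_per_min=go["blink_base_per_min"], arousal_gain=go["arousal_blink_gain"]))
    last_track = -np.inf
    last_emblem = -np.inf
    prev_wave = prev_smile = prev_invading = False
    last_au: dict | None = None
    radius = so["personal_space_radius"]

    for i in range(n):
        clock = i * dt
        user = _input_at(user_stream, i)
        triggers: list[Trigger] = []

        # --- game FSM ---
        if machine is not None and machine.state is not GameState.WAIT:
            _, events, requests = machine.step(user, clock)
            for ev in events:
                log.events.append(ev)
                if ev["event"] in GAME_EVENTS:
                    triggers.extend(rps_event_to_triggers(
                        ev["event"], time=clock,
                        round_index=ev.get("round", 0),
                        magnitudes=eo["trigger_magnitudes"],
                    ))
                if ev["event"] == "agent_play_hand":
                    attention.raise_event("agent_play_hand", clock)
            for req in requests:
                scheduler.submit(req)

        # --- user feedback edges ---
        if user.waving and not prev_wave:
            triggers.extend(rps_event_to_triggers("user_wave", time=clock,
                                                  magnitudes=eo["trigger_magnitudes"]))
            attention.raise_event("user_wave", clock)
            log.events.append({"event": "user_wave", "time": clock})
        wave_back = gestures.maybe_wave(user.waving, clock)
        if wave_back is not None:
            scheduler.submit(gesture_request(wave_back, Priority.HIGH))
        if user.smiling and not prev_smile:
            triggers.extend(rps_event_to_triggers("user_smile", time=clock,
                                                  magnitudes=eo["trigger_magnitudes"]))
            log.events.append({"event": "user_smile", "time": clock})
        invading = float(np.hypot(*user.position)) < radius
        if invading and not prev_invading:
            triggers.extend(rps_event_to_triggers("space_invasion", time=clock,
                                                  magnitudes=eo["trigger_magnitudes"]))
            attention.raise_event("space_invasion", clock)
            log.events.append({"event": "space_invasion", "time": clock})
        prev_wave, prev_smile, prev_invading = user.waving, user.smiling, invading

        # --- affect integration ---
        state = step_affect(state, triggers, affect_params, dt, rng_affect,
                            weights=eo["trigger_weights"])
        trace.append(state)

        # --- reactive gaze: follow a moving user ---
        if user.moving and clock - last_track > 0.5:
            ev = gaze_mod.reactive_gaze(user.position, time=clock,
                                        head_speed=gaze_params.head_speed)
            scheduler.submit(gaze_request(ev, Priority.HIGH))
            last_track = clock

        # --- idle gaze ---
        if clock >= next_gaze_decision:
            ev = gaze_mod.idle_gaze_step("mutual", gaze_params, rng_gaze, time=clock)
            req = gaze_request(ev, Priority.LOW)
            if attention_gate(req, attention.flags, clock):
                scheduler.submit(req)
            hold = rng_gaze.exponential(60.0 / gaze_params.avert_frequency)
            next_gaze_decision = clock + ev.duration + hold

        # --- blinking (overlays everything; not a scheduling contender) ---
        while next_blink <= clock:
            log.blinks.append(gaze_mod.blink_event(next_blink, gaze_params))
            next_blink += float(gaze_mod.blink_interval(
                state.arousal, gaze_params, rng_blink,
                base_per_min=go["blink_base_per_min"],
                arousal_gain=go["arousal_blink_gain"]))

        # --- face ---
        vl = face_mod.quantize_va(state.valence)
        al = face_mod.quantize_va(state.arousal)
        raw = face_mod.va_to_au(vl, al, au_map)
        expressed = face_mod.apply_personality_face(raw, face_params,
                                                    twitch=twitcher.current(clock))
        log.au_intensity_trace.append(
            float(np.mean(list(expressed.values()))) if expressed else 0.0
        )
        if expressed != last_au:
            req = _face_request(expressed, clock)
            scheduler.submit(req)
            last_au = expressed

        # --- idle gestures, emblems, body twitches ---
        idle = gestures.maybe_idle(state, clock)
        if idle is not None:
            req = gesture_request(idle, Priority.LOW)
            if attention_gate(req, attention.flags, clock):
                scheduler.submit(req)
        emblem = emblem_for_emotion(state, geo["emblem_valence_max"],
                                    geo["emblem_arousal_min"], time=clock)
        if emblem is not None and clock - last_emblem > 5.0:
            scheduler.submit(gesture_request(emblem, Priority.MID))
            frowning = any(u in expressed for u in (1, 4, 15))
            log.events.append({"event": "emblem_fist", "time": clock,
                               "frowning_face": frowning})
            last_emblem = clock
        while (twitch_cursor < len(body_twitches)
               and body_twitches[twitch_cursor].time <= clock):
            tw = body_twitches[twitch_cursor]
            req = gesture_request(tw, Priority.LOW)
            if attention_gate(req, attention.flags, clock):
                scheduler.submit(req)
            twitch_cursor += 1

        # --- arbitration ---
        attention.tick(clock)
        decisions = scheduler.resolve(clock)
        log.commands.extend(d for d in decisions if d.outcome in ("emitted", "blended", "deferred"))

    # renumber request ids in submission order so logs are reproducible
    id_map: dict[int, int] = {}
    for cmd in scheduler.audit:
        id_map.setdefault(cmd.request.id, len(id_map) + 1)
    for cmd in scheduler.audit:
        cmd.request.id = id_map[cmd.request.id]
    log.audit = scheduler.audit
    log.face_twitch_count = twitcher.count
    return log


def _face_request(expressed: dict, clock: float):
    from .executive import BehaviourRequest
    return BehaviourRequest(
        modality=Modality.FACE,
        actuators=frozenset({"face_upper", "face_lower"}),
        priority=Priority.LOW,
        requested_onset=clock,
        duration=0.5,
        payload=dict(expressed),
    )


def summarize(log: BehaviourLog) -> BehaviourSummary:
    """Reduce a behaviour log to the personality-bearing statistics."""
    if len(log.trace) == 0:
        raise ValueError("empty behaviour log")
    minutes = log.config.duration / 60.0

    idle_gaze = [c for c in log.commands
                 if isinstance(c.request.payload, gaze_mod.GazeEvent)
                 and c.request.payload.kind == "idle_saccade"]
    mutual_time = sum(c.request.payload.duration for c in idle_gaze
                      if c.request.payload.gaze_state == "mutual")
    total_time = sum(c.request.payload.duration for c in idle_gaze)
    mutual_frac = mutual_time / total_time if total_time > 0 else 0.0

    from .gesture import GestureEvent
    idle_g = [c.request.payload for c in log.commands
              if isinstance(c.request.payload, GestureEvent)
              and c.request.payload.kind in ("posture_shift", "self_adaptor")]
    shifts = sum(1 for g in idle_g if g.kind == "posture_shift")
    body_twitches = sum(1 for c in log.commands
                        if isinstance(c.request.payload, GestureEvent)
                        and c.request.payload.kind == "body_twitch")

    mean_v, mean_a = affect_attractor(log.trace)
    return BehaviourSummary(
        blink_rate=len(log.blinks) / minutes,
        mutual_gaze_fraction=mutual_frac,
        posture_shift_fraction=shifts / len(idle_g) if idle_g else 0.0,
        idle_gesture_rate=len(idle_g) / minutes,
        twitch_count=body_twitches + log.face_twitch_count,
        mean_valence=mean_v,
        mean_arousal=mean_a,
        mean_au_intensity=float(np.mean(log.au_intensity_trace)) if log.au_intensity_trace else 0.0,
    )


def build_centroids(
    runs_per_category: int = 10,
    base_seed: int = 1000,
    duration: float = 120.0,
    scenario: str = "rps",
) -> dict:
    """Reference summary centroids from seeded runs of every category.

    Returns a dict with per-category feature means plus the pooled
    per-feature mean/std used for standardization.
    """
    vectors: dict[str, list[np.ndarray]] = {}
    for ci, category in enumerate(PersonalityCategory):
        rows = []
        for r in range(runs_per_category):
            cfg = SessionConfig(personality=category, duration=duration,
                                seed=base_seed + 100 * ci + r, scenario=scenario)
            rows.append(summarize(run_session(cfg)).as_vector())
        vectors[category.value] = rows
    pooled = np.vstack([np.vstack(rows) for rows in vectors.values()])
    scale_mean = pooled.mean(axis=0)
    scale_std = pooled.std(axis=0, ddof=1)
    return {
        "features": list(SUMMARY_FEATURES),
        "scale_mean": scale_mean.tolist(),
        "scale_std": scale_std.tolist(),
        "centroids": {cat: np.vstack(rows).mean(axis=0).tolist()
                      for cat, rows in vectors.items()},
    }


def save_centroids(centroids: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(centroids, fh, indent=1)


def load_centroids(path=None) -> dict:
    if path is None:
        import importlib.resources
        text = (importlib.resources.files("personasim.data")
                .joinpath("centroids.json").read_text())
        return json.loads(text)
    with open(path) as fh:
        return json.load(fh)


def classify_personality(summary: BehaviourSummary, centroids: dict) -> PersonalityCategory:
    """Nearest-centroid category assignment in standardized summary space."""
    features = centroids["features"]
    mean = np.asarray(centroids["scale_mean"], dtype=float)
    std = np.asarray(centroids["scale_std"], dtype=float)
    keep = std > 1e-12
    if not keep.all():
        dropped = [f for f, k in zip(features, keep) if not k]
        warnings.warn(f"excluding zero-variance features {dropped}")
    vec = summary.as_vector()
    z = (vec[keep] - mean[keep]) / std[keep]
    best, best_dist = None, np.inf
    for cat, centroid in centroids["centroids"].items():
        c = np.asarray(centroid, dtype=float)
        cz = (c[keep] - mean[keep]) / std[keep]
        dist = float(np.linalg.norm(z - cz))
        if dist < best_dist:
            best, best_dist = cat, dist
    return PersonalityCategory(best)
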