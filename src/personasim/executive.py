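"""Attention gating and priority scheduling of behaviour requests.

Several controllers propose behaviour concurrently (idle gaze, idle
gestures, reactive waves, communicative game acts).  Two mechanisms keep
the output coherent on a shared body:

* **Attention flags** — scoped (gaze / body / both), time-limited
  suppressors raised by attention-worthy events.  While a flag is live,
  idle behaviour in its scope is withheld so it cannot blend into the
  deliberate act; other body parts carry on.
* **A three-queue priority scheduler** — every request is high, mid or
  low priority.  High requests run at their requested onset and preempt
  conflicting lower-priority commands.  Mid requests are shifted to the
  earliest conflict-free onset, and dropped if the shift would exceed
  ``defer_limit``.  Low (idle) requests blend with other low commands,
  and are dropped when they would collide with anything higher — their
  loss is imperceptible by design.

Actuator names are an 8-way body-resource taxonomy; a non-blended command
owns its actuators for its whole duration.
"""
from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

__all__ = [
    "ACTUATORS",
    "Priority",
    "Modality",
    "BehaviourRequest",
    "AttentionFlag",
    "AttentionController",
    "ScheduledCommand",
    "Scheduler",
    "raise_attention",
    "attention_gate",
    "schedule",
]

ACTUATORS = frozenset(
    {"eyes", "head", "torso", "left_arm", "right_arm", "face_upper", "face_lower", "legs"}
)

#: Which scope an attention-worthy event raises. Gaze-directed acts only
#: pin the gaze; a wave from the user demands the whole body's attention.
DEFAULT_ATTENTION_SCOPES = {
    "user_wave": "both",
    "agent_play_hand": "gaze",
    "space_invasion": "body",
}


class Priority(enum.IntEnum):
    LOW = 0
    MID = 1
    HIGH = 2


class Modality(str, enum.Enum):
    GAZE = "gaze"
    FACE = "face"
    GESTURE = "gesture"
    POSTURE = "posture"


_ids = itertools.count(1)


@dataclass
class BehaviourRequest:
    modality: Modality
    actuators: frozenset
    priority: Priority
    requested_onset: float
    duration: float
    payload: Any = None
    id: int = field(default_factory=lambda: next(_ids))

    def __post_init__(self) -> None:
        if not self.actuators:
            raise ValueError("behaviour request must claim at least one actuator")
        unknown = set(self.actuators) - ACTUATORS
        if unknown:
            raise ValueError(f"unknown actuators {unknown}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class AttentionFlag:
    scope: str           # "gaze" | "body" | "both"
    phase: str           # "establishing" | "maintaining" | "ending"
    expiry: float

    def covers(self, modality: Modality) -> bool:
        if self.scope == "both":
            return modality in (Modality.GAZE, Modality.GESTURE, Modality.POSTURE)
        if self.scope == "gaze":
            return modality is Modality.GAZE
        return modality in (Modality.GESTURE, Modality.POSTURE)

    def active(self, clock: float) -> bool:
        return clock < self.expiry


def raise_attention(
    event: str,
    clock: float,
    hold: float = 3.0,
    scopes: dict | None = None,
) -> AttentionFlag:
    """Create an attention flag for an attention-worthy event."""
    if hold <= 0:
        raise ValueError("hold must be positive")
    table = scopes if scopes is not None else DEFAULT_ATTENTION_SCOPES
    scope = table.get(event, "both")
    return AttentionFlag(scope=scope, phase="establishing", expiry=clock + hold)


class AttentionController:
    """Tracks live attention flags; renewal before expiry extends a flag."""

    def __init__(self, hold: float = 3.0, scopes: dict | None = None):
        self.hold = hold
        self.scopes = scopes if scopes is not None else DEFAULT_ATTENTION_SCOPES
        self.flags: list[AttentionFlag] = []

    def raise_event(self, event: str, clock: float) -> AttentionFlag:
        scope = self.scopes.get(event, "both")
        for flag in self.flags:
            if flag.scope == scope and flag.active(clock):
                flag.expiry = clock + self.hold
                flag.phase = "maintaining"
                return flag
        flag = raise_attention(event, clock, self.hold, self.scopes)
        self.flags.append(flag)
        return flag

    def tick(self, clock: float) -> None:
        for flag in self.flags:
            if flag.phase == "establishing":
                flag.phase = "maintaining"
            if not flag.active(clock):
                flag.phase = "ending"
        self.flags = [f for f in self.flags if f.active(clock)]


def attention_gate(
    request: BehaviourRequest,
    flags: Iterable[AttentionFlag],
    clock: float,
) -> bool:
    """True if the request may proceed, False if suppressed.

    Only idle (low-priority) requests are ever suppressed, and only while
    a live flag's scope covers their modality.
    """
    if request.priority is not Priority.LOW:
        return True
    for flag in flags:
        if flag.active(clock) and flag.covers(request.modality):
            return False
    return True


@dataclass
class ScheduledCommand:
    request: BehaviourRequest
    scheduled_onset: float
    outcome: str  # "emitted" | "deferred" | "dropped" | "blended"

    @property
    def end(self) -> float:
        return self.scheduled_onset + self.request.duration

    def overlaps(self, onset: float, duration: float) -> bool:
        return self.scheduled_onset < onset + duration and onset < self.end


def _conflicts(
    active: list[ScheduledCommand], onset: float, request: BehaviourRequest
) -> list[ScheduledCommand]:
    return [
        cmd
        for cmd in active
        if cmd.outcome in ("emitted", "deferred", "blended")
        and cmd.request.actuators & request.actuators
        and cmd.overlaps(onset, request.duration)
    ]


def _earliest_free(
    active: list[ScheduledCommand],
    request: BehaviourRequest,
    not_before: float,
    against: Optional[list[ScheduledCommand]] = None,
) -> float:
    """Earliest onset >= not_before with no actuator conflict."""
    pool = active if against is None else against
    t = not_before
    # candidate onsets are the requested time and ends of conflicting intervals
    for _ in range(len(pool) + 1):
        clash = _conflicts(pool, t, request)
        if not clash:
            return t
        t = max(cmd.end for cmd in clash)
    return t


def schedule(
    queues: dict[Priority, list[BehaviourRequest]],
    active: list[ScheduledCommand],
    clock: float,
    defer_limit: float = 2.0,
) -> list[ScheduledCommand]:
    """Resolve one batch of queued requests against the active commands.

    ``active`` is mutated: preempted commands are re-marked "dropped".
    Returns the scheduling decisions for the batch in processing order.
    Ties within a priority class break by requested onset, then insertion
    order (queues are FIFO lists).
    """
    decisions: list[ScheduledCommand] = []
    for priority in (Priority.HIGH, Priority.MID, Priority.LOW):
        batch = sorted(
            enumerate(queues.get(priority, [])), key=lambda p: (p[1].requested_onset, p[0])
        )
        for _, req in batch:
            onset = max(req.requested_onset, clock)
            if priority is Priority.HIGH:
                # defer only past equal-priority work, then preempt whatever
                # lower-priority commands conflict at the chosen onset
                peers = [c for c in active
                         if c.outcome in ("emitted", "deferred", "blended")
                         and c.request.priority >= Priority.HIGH]
                start = _earliest_free(active, req, onset, against=peers)
                for cmd in _conflicts(active, start, req):
                    if cmd.request.priority < Priority.HIGH:
                        cmd.outcome = "dropped"
                cmd = ScheduledCommand(req, start, "emitted")
                active.append(cmd)
                decisions.append(cmd)
            elif priority is Priority.MID:
                start = _earliest_free(active, req, onset)
                if start - onset > defer_limit:
                    decisions.append(ScheduledCommand(req, onset, "dropped"))
                    continue
                outcome = "emitted" if start == onset else "deferred"
                cmd = ScheduledCommand(req, start, outcome)
                active.append(cmd)
                decisions.append(cmd)
            else:
                clash = _conflicts(active, onset, req)
                if any(c.request.priority > Priority.LOW for c in clash):
                    decisions.append(ScheduledCommand(req, onset, "dropped"))
                elif clash:
                    cmd = ScheduledCommand(req, onset, "blended")
                    active.append(cmd)
                    decisions.append(cmd)
                else:
                    cmd = ScheduledCommand(req, onset, "emitted")
                    active.append(cmd)
                    decisions.append(cmd)
    for priority in queues:
        queues[priority] = []
    return decisions


class Scheduler:
    """Stateful wrapper: accumulates requests, resolves per tick, keeps an audit."""

    def __init__(self, defer_limit: float = 2.0):
        self.defer_limit = defer_limit
        self.queues: dict[Priority, list[BehaviourRequest]] = {
            Priority.HIGH: [], Priority.MID: [], Priority.LOW: []
        }
        self.active: list[ScheduledCommand] = []
        self.audit: list[ScheduledCommand] = []

    def submit(self, request: BehaviourRequest) -> None:
        self.queues[request.priority].append(request)

    def resolve(self, clock: float) -> list[ScheduledCommand]:
        self.active = [c for c in self.active if c.end > clock and c.outcome != "dropped"]
        decisions = schedule(self.queues, self.active, clock, self.defer_limit)
        self.audit.extend(decisions)
        return decisions
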