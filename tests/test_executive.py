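"""Attention gating and the priority scheduler, checked against a
grid-search oracle on small randomized instances."""
import numpy as np
import pytest

from personasim.executive import (
    AttentionController,
    BehaviourRequest,
    Modality,
    Priority,
    ScheduledCommand,
    attention_gate,
    raise_attention,
    schedule,
)


def req(modality, actuators, priority, onset, duration=1.0):
    return BehaviourRequest(
        modality=Modality(modality), actuators=frozenset(actuators),
        priority=priority, requested_onset=onset, duration=duration,
    )


# ---------------------------------------------------------------- attention

def test_attention_scopes_per_event():
    assert raise_attention("user_wave", 0.0).scope == "both"
    assert raise_attention("agent_play_hand", 0.0).scope == "gaze"
    assert raise_attention("space_invasion", 0.0).scope == "body"


def test_renewal_extends_expiry():
    controller = AttentionController(hold=3.0)
    flag = controller.raise_event("user_wave", 0.0)
    assert flag.expiry == 3.0
    renewed = controller.raise_event("user_wave", 2.0)
    assert renewed is flag and flag.expiry == 5.0


def test_gate_suppresses_idle_in_scope_only():
    flag = raise_attention("agent_play_hand", 0.0, hold=3.0)  # gaze scope
    idle_gaze = req("gaze", {"eyes"}, Priority.LOW, 1.0)
    idle_gesture = req("gesture", {"right_arm"}, Priority.LOW, 1.0)
    communicative = req("gaze", {"eyes"}, Priority.MID, 1.0)
    assert not attention_gate(idle_gaze, [flag], 1.0)
    assert attention_gate(idle_gesture, [flag], 1.0)       # body parts carry on
    assert attention_gate(communicative, [flag], 1.0)      # never gates non-idle
    assert attention_gate(idle_gaze, [flag], 3.5)          # expired flag


def test_both_scope_covers_gaze_and_body():
    flag = raise_attention("user_wave", 0.0)
    assert not attention_gate(req("gaze", {"eyes"}, Priority.LOW, 0.5), [flag], 0.5)
    assert not attention_gate(req("posture", {"torso"}, Priority.LOW, 0.5), [flag], 0.5)


def test_invalid_hold_rejected():
    with pytest.raises(ValueError):
        raise_attention("user_wave", 0.0, hold=0.0)


# ---------------------------------------------------------------- scheduler

def run_batch(requests, defer_limit=2.0):
    queues = {Priority.HIGH: [], Priority.MID: [], Priority.LOW: []}
    for r in requests:
        queues[r.priority].append(r)
    active: list[ScheduledCommand] = []
    decisions = schedule(queues, active, clock=0.0, defer_limit=defer_limit)
    return {d.request.id: d for d in decisions}


def test_high_wave_preempts_low_scratch_on_shared_arm():
    wave = req("gesture", {"left_arm"}, Priority.HIGH, 0.0)
    scratch = req("gesture", {"left_arm"}, Priority.LOW, 0.0)
    out = run_batch([scratch, wave])
    assert out[wave.id].outcome == "emitted"
    assert out[scratch.id].outcome == "dropped"


def test_disjoint_actuators_run_in_parallel():
    avert = req("gaze", {"head"}, Priority.LOW, 0.0)
    scratch = req("gesture", {"right_arm"}, Priority.LOW, 0.0)
    out = run_batch([avert, scratch])
    assert out[avert.id].outcome == "emitted"
    assert out[scratch.id].outcome == "emitted"


def test_mid_defers_then_drops_beyond_limit():
    blocker = req("gesture", {"right_arm"}, Priority.HIGH, 0.0, duration=1.5)
    soon = req("gesture", {"right_arm"}, Priority.MID, 0.0, duration=1.0)
    out = run_batch([blocker, soon], defer_limit=2.0)
    assert out[soon.id].outcome == "deferred"
    assert out[soon.id].scheduled_onset == pytest.approx(1.5)

    long_blocker = req("gesture", {"right_arm"}, Priority.HIGH, 0.0, duration=3.0)
    out = run_batch([long_blocker, soon], defer_limit=2.0)
    assert out[soon.id].outcome == "dropped"


def test_low_blends_with_low():
    shift = req("posture", {"torso"}, Priority.LOW, 0.0, duration=2.0)
    twitch = req("gesture", {"torso"}, Priority.LOW, 0.5, duration=0.5)
    out = run_batch([shift, twitch])
    assert out[shift.id].outcome == "emitted"
    assert out[twitch.id].outcome == "blended"


def test_preempted_command_is_dropped_not_paused():
    active = [ScheduledCommand(req("gesture", {"left_arm"}, Priority.LOW, 0.0, 3.0),
                               0.0, "emitted")]
    queues = {Priority.HIGH: [req("gesture", {"left_arm"}, Priority.HIGH, 1.0, 1.0)],
              Priority.MID: [], Priority.LOW: []}
    decisions = schedule(queues, active, clock=1.0)
    assert decisions[0].outcome == "emitted"
    assert active[0].outcome == "dropped"


# ------------------------------------------------------- oracle equivalence

GRID = 0.05


def oracle_schedule(requests, defer_limit=2.0):
    """Independent re-derivation: earliest feasible onsets found by scanning
    a fine time grid, applying the priority rules declaratively."""
    active = []   # (onset, request)
    outcome = {}
    onset_of = {}

    def conflicts(t, request, pool):
        out = []
        for onset, other in pool:
            if onset < t + request.duration and t < onset + other.duration \
                    and other.actuators & request.actuators:
                out.append((onset, other))
        return out

    order = sorted(requests, key=lambda r: (-int(r.priority), r.requested_onset, r.id))
    for r in order:
        t0 = r.requested_onset
        if r.priority is Priority.HIGH:
            # fit among the other highs first, then preempt lower work there
            highs = [(o, x) for o, x in active if x.priority is Priority.HIGH]
            t = t0
            while conflicts(t, r, highs):
                t = round(t + GRID, 10)
            for onset, other in conflicts(t, r, active):
                if other.priority < Priority.HIGH:
                    outcome[other.id] = "dropped"
                    active.remove((onset, other))
            outcome[r.id], onset_of[r.id] = "emitted", t
            active.append((t, r))
        elif r.priority is Priority.MID:
            t = t0
            while conflicts(t, r, active) and t - t0 <= defer_limit:
                t = round(t + GRID, 10)
            if t - t0 > defer_limit or conflicts(t, r, active):
                outcome[r.id], onset_of[r.id] = "dropped", t0
            else:
                outcome[r.id] = "emitted" if t == t0 else "deferred"
                onset_of[r.id] = t
                active.append((t, r))
        else:
            clash = conflicts(t0, r, active)
            if any(other.priority > Priority.LOW for _, other in clash):
                outcome[r.id], onset_of[r.id] = "dropped", t0
            elif clash:
                outcome[r.id], onset_of[r.id] = "blended", t0
                active.append((t0, r))
            else:
                outcome[r.id], onset_of[r.id] = "emitted", t0
                active.append((t0, r))
    return outcome, onset_of


def random_instance(rng):
    actuators = ["eyes", "head", "torso", "right_arm"][: int(rng.integers(2, 5))]
    n = int(rng.integers(2, 9))
    reqs = []
    for _ in range(n):
        acts = frozenset(rng.choice(actuators,
                                    size=int(rng.integers(1, len(actuators) + 1)),
                                    replace=False))
        reqs.append(BehaviourRequest(
            modality=Modality.GESTURE, actuators=acts,
            priority=Priority(int(rng.integers(3))),
            requested_onset=float(rng.integers(0, 5)) * 0.5,
            duration=float(rng.integers(1, 5)) * 0.5,
        ))
    return reqs


def test_scheduler_matches_grid_search_oracle():
    """On randomized small instances the scheduler equals the oracle exactly."""
    rng = np.random.default_rng(77)
    for _ in range(300):
        reqs = random_instance(rng)
        got = run_batch(reqs)
        want_outcome, want_onset = oracle_schedule(reqs)
        for r in reqs:
            assert got[r.id].outcome == want_outcome[r.id], (r, got[r.id])
            if got[r.id].outcome != "dropped":
                assert got[r.id].scheduled_onset == pytest.approx(want_onset[r.id])


def test_no_overlapping_nonblended_actuator_claims():
    """Emitted (non-blended) commands never share an actuator while overlapping."""
    rng = np.random.default_rng(78)
    for _ in range(200):
        decisions = run_batch(random_instance(rng))
        emitted = [d for d in decisions.values() if d.outcome in ("emitted", "deferred")]
        for i, a in enumerate(emitted):
            for b in emitted[i + 1:]:
                if a.request.actuators & b.request.actuators:
                    assert not a.overlaps(b.scheduled_onset, b.request.duration)


def test_high_never_dropped_and_mid_starvation_bounded():
    rng = np.random.default_rng(79)
    for _ in range(200):
        decisions = run_batch(random_instance(rng), defer_limit=2.0)
        for d in decisions.values():
            if d.request.priority is Priority.HIGH:
                assert d.outcome == "emitted"
            if d.request.priority is Priority.MID and d.outcome != "dropped":
                assert d.scheduled_onset - d.request.requested_onset <= 2.0 + 1e-9
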