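"""Valence-arousal dynamics: triggers, integration, attractors."""
import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from personasim.core import PersonalityCategory as PC
from personasim.emotion import (
    AffectState,
    AffectTrace,
    NeedLevel,
    Trigger,
    affect_attractor,
    rps_event_to_triggers,
    step_affect,
    trigger_weight,
)


def test_need_weights_follow_maslow_ordering():
    assert trigger_weight("safety") > trigger_weight("belonging") > trigger_weight("esteem") > 0
    custom = {"safety": 2.0, "belonging": 1.0, "esteem": 0.5}
    assert trigger_weight(NeedLevel.SAFETY, custom) == 2.0
    with pytest.raises(ValueError):
        trigger_weight("greed")


@pytest.mark.parametrize(
    "event,channel,sign,need",
    [
        ("agent_win", "valence", +1, NeedLevel.ESTEEM),
        ("agent_lose", "valence", -1, NeedLevel.ESTEEM),
        ("user_wave", "valence", +1, NeedLevel.BELONGING),
        ("user_smile", "valence", +1, NeedLevel.BELONGING),
        ("approach_go", "arousal", +1, NeedLevel.ESTEEM),
        ("enter_wait", "arousal", -1, NeedLevel.ESTEEM),
        ("space_invasion", "arousal", +1, NeedLevel.SAFETY),
    ],
)
def test_event_trigger_mapping(event, channel, sign, need):
    (trig,) = rps_event_to_triggers(event)
    assert (trig.channel, trig.sign, trig.need_level) == (channel, sign, need)


def test_draw_has_no_affect_consequence():
    assert rps_event_to_triggers("draw") == []


def test_space_invasion_outweighs_esteem_triggers():
    (inv,) = rps_event_to_triggers("space_invasion")
    (win,) = rps_event_to_triggers("agent_win")
    assert trigger_weight(inv.need_level) > trigger_weight(win.need_level)


def test_cycle_repeat_magnitude_scales_and_caps():
    (t1,) = rps_event_to_triggers("cycle_repeat", round_index=1)
    (t3,) = rps_event_to_triggers("cycle_repeat", round_index=3)
    (t9,) = rps_event_to_triggers("cycle_repeat", round_index=9)
    assert t1.magnitude == pytest.approx(0.2)
    assert t3.magnitude == pytest.approx(0.6)
    assert t9.magnitude == 1.0
    assert t3.sign == -1 and t3.channel == "arousal"


def test_unknown_event_rejected():
    with pytest.raises(ValueError):
        rps_event_to_triggers("meteor_strike")


def _params(all_params, cat):
    return all_params[cat][0]


def test_single_euler_step_matches_hand_computation(all_params):
    """One step, Neutral defaults, V=0, one (+valence, esteem, mag 1) trigger.

    Hand calculation with the shipped constants: decay term is zero at
    baseline, impulse adds w(esteem) * gain_pos * 1 = 0.3 * 1.0 = 0.3.
    """
    params = _params(all_params, PC.NEUTRAL)
    trig = Trigger(0.0, NeedLevel.ESTEEM, "valence", +1, 1.0)
    out = step_affect(AffectState(0.0, 0.0), [trig], params, dt=0.1)
    assert out.valence == pytest.approx(0.3, abs=1e-12)
    assert out.arousal == pytest.approx(0.0)


def test_baseline_is_fixed_point(all_params):
    for cat in PC:
        p = _params(all_params, cat)
        lab0 = dataclasses.replace(p, lability=0.0)
        s = AffectState(p.baseline_valence, p.baseline_arousal)
        out = step_affect(s, [], lab0, dt=0.1)
        assert out.valence == pytest.approx(s.valence)
        assert out.arousal == pytest.approx(s.arousal)


def test_positive_response_larger_for_hehs_than_lels(all_params):
    trig = Trigger(0.0, NeedLevel.ESTEEM, "valence", +1, 1.0)
    deltas = {}
    for cat in (PC.HEHS, PC.LELS):
        p = _params(all_params, cat)
        out = step_affect(AffectState(0.0, 0.0), [trig], p, dt=0.1,
                          rng=np.random.default_rng(0))
        deltas[cat] = out.valence
    assert deltas[PC.HEHS] > deltas[PC.LELS]


def test_reaction_asymmetry(all_params):
    """HEHS reacts more to positive than negative triggers; LELS reversed."""
    pos = Trigger(0.0, NeedLevel.ESTEEM, "valence", +1, 0.5)
    neg = Trigger(0.0, NeedLevel.ESTEEM, "valence", -1, 0.5)
    for cat, positive_dominant in ((PC.HEHS, True), (PC.LELS, False)):
        p = _params(all_params, cat)
        lab0 = dataclasses.replace(p, lability=0.0)
        up = step_affect(AffectState(0.0, 0.0), [pos], lab0, 0.1).valence
        down = -step_affect(AffectState(0.0, 0.0), [neg], lab0, 0.1).valence
        assert (up > down) is positive_dominant


def test_dt_must_be_positive(all_params):
    with pytest.raises(ValueError):
        step_affect(AffectState(0, 0), [], _params(all_params, PC.NEUTRAL), dt=0.0)


@given(
    v0=st.floats(-1, 1, allow_nan=False),
    a0=st.floats(-1, 1, allow_nan=False),
    signs=st.lists(st.sampled_from([+1, -1]), min_size=0, max_size=30),
)
def test_boundedness_under_arbitrary_trigger_streams(all_params, v0, a0, signs):
    """Valence and arousal never leave [-1, 1], whatever the stream."""
    p = _params(all_params, PC.HELS)
    rng = np.random.default_rng(7)
    state = AffectState(v0, a0)
    for i, sign in enumerate(signs):
        trig = Trigger(i * 0.1, NeedLevel.SAFETY, "valence" if i % 2 else "arousal",
                       sign, 1.0)
        state = step_affect(state, [trig], p, dt=0.1, rng=rng)
        assert -1.0 <= state.valence <= 1.0
        assert -1.0 <= state.arousal <= 1.0


def test_baseline_recovery_is_monotone(all_params):
    """After triggers cease (lability 0), distance to baseline strictly shrinks."""
    p = _params(all_params, PC.HEHS)
    lab0 = dataclasses.replace(p, lability=0.0)
    state = AffectState(1.0, -1.0)
    dist = math.hypot(state.valence - p.baseline_valence,
                      state.arousal - p.baseline_arousal)
    for _ in range(2000):
        state = step_affect(state, [], lab0, dt=0.1)
        new = math.hypot(state.valence - p.baseline_valence,
                         state.arousal - p.baseline_arousal)
        if new < 1e-6:
            break
        assert new < dist
        dist = new
    assert dist < 1e-2


def _balanced_stream(n_pairs=30, period=10.0):
    trigs = []
    for k in range(n_pairs):
        trigs.append((k * period + 2.0,
                      Trigger(0, NeedLevel.ESTEEM, "valence", +1, 1.0)))
        trigs.append((k * period + 7.0,
                      Trigger(0, NeedLevel.ESTEEM, "valence", -1, 1.0)))
    return trigs


def _simulate(params, stream, duration=300.0, dt=0.1, seed=11):
    rng = np.random.default_rng(seed)
    state = AffectState(params.baseline_valence, params.baseline_arousal)
    trace = AffectTrace(dt)
    trace.append(state)
    pending = sorted(stream, key=lambda p: p[0])
    j = 0
    for i in range(int(duration / dt)):
        t = i * dt
        now = []
        while j < len(pending) and pending[j][0] <= t:
            now.append(pending[j][1])
            j += 1
        state = step_affect(state, now, params, dt, rng)
        trace.append(state)
    return trace


def test_attractor_ordering_under_balanced_stream(all_params):
    """Equal counts of +/- events still leave HEHS > Neutral > LELS in valence."""
    stream = _balanced_stream()
    means = {}
    for cat in (PC.HEHS, PC.NEUTRAL, PC.LELS):
        trace = _simulate(_params(all_params, cat), stream)
        means[cat], _ = affect_attractor(trace, burn_in=30.0)
    assert means[PC.HEHS] > means[PC.NEUTRAL] > means[PC.LELS]


def test_arousal_baseline_signs(all_params):
    """With no triggers the arousal attractor carries the table's sign."""
    expected_sign = {PC.HELS: 1, PC.HEHS: -1, PC.LELS: 1, PC.LEHS: -1, PC.NEUTRAL: 0}
    for cat, sign in expected_sign.items():
        trace = _simulate(_params(all_params, cat), [], duration=120.0)
        _, mean_a = affect_attractor(trace, burn_in=10.0)
        if sign == 0:
            assert abs(mean_a) < 0.05
        else:
            assert np.sign(mean_a) == sign


def test_lability_drives_valence_change_frequency(all_params):
    """High change-frequency categories reverse valence direction far more often."""
    reversals = {}
    for cat in PC:
        trace = _simulate(_params(all_params, cat), [], duration=600.0, seed=5)
        dv = np.diff(np.asarray(trace.valence))
        dv = dv[np.abs(dv) > 1e-12]
        reversals[cat] = int(np.sum(np.diff(np.sign(dv)) != 0))
    for high in (PC.HELS, PC.LELS):
        for low in (PC.HEHS, PC.LEHS):
            assert reversals[high] > reversals[low]


def test_attractor_of_constant_trace():
    trace = AffectTrace(0.1)
    for i in range(100):
        trace.append(AffectState(0.3, -0.2, i * 0.1))
    assert affect_attractor(trace) == pytest.approx((0.3, -0.2))


def test_attractor_requires_samples():
    trace = AffectTrace(0.1)
    trace.append(AffectState(0, 0, 0.0))
    with pytest.raises(ValueError):
        affect_attractor(trace, burn_in=10.0)


def test_paired_seeded_streams_order_lels_below_hehs(all_params):
    stream = _balanced_stream(n_pairs=20)
    t_lels = _simulate(_params(all_params, PC.LELS), stream, seed=42)
    t_hehs = _simulate(_params(all_params, PC.HEHS), stream, seed=42)
    assert affect_attractor(t_lels, 20.0)[0] < affect_attractor(t_hehs, 20.0)[0]


def test_trace_csv_roundtrip(tmp_path):
    trace = AffectTrace(0.1)
    for i in range(50):
        trace.append(AffectState(np.sin(i / 10), np.cos(i / 10) * 0.5, i * 0.1))
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    back = AffectTrace.from_csv(path)
    assert np.allclose(back.valence, trace.valence)
    assert np.allclose(back.times, trace.times)
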