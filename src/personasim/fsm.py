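"""Turn-taking control of the rock-paper-scissors interaction.

A five-state machine drives each game round: Ready (wait for the user to
stand still) -> Go (the agent commits to a random hand) -> Hands (both
parties show their hand) -> Result (judge, update the tally) and back to
Ready for the next round, or to a terminal Wait state when the session's
rounds are exhausted.  Stepping the machine yields game events (which
the emotion module turns into affect triggers) and communicative
behaviour requests (the agent's hand gesture, glances at the user's hand
and at the GUI scoreboard).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .executive import BehaviourRequest, Modality, Priority
from .gaze import GazeEvent, communicative_gaze
from .gesture import GestureEvent, communicative_gesture
from .core import GestureParams

__all__ = [
    "GameState",
    "UserInput",
    "RoundOutcome",
    "HANDS",
    "agent_hand_choice",
    "judge_round",
    "RPSInteraction",
    "fsm_step",
    "gaze_request",
    "gesture_request",
]

HANDS = ("rock", "paper", "scissors")

#: what each hand defeats
_BEATS = {"rock": "scissors", "scissors": "paper", "paper": "rock"}

DEFAULT_DWELL = {"Ready": 2.0, "Go": 1.0, "Hands": 1.5, "Result": 2.0}


class GameState(str, enum.Enum):
    READY = "Ready"
    GO = "Go"
    HANDS = "Hands"
    RESULT = "Result"
    WAIT = "Wait"


class RoundOutcome(str, enum.Enum):
    AGENT_WIN = "agent_win"
    USER_WIN = "user_win"
    DRAW = "draw"


@dataclass(frozen=True)
class UserInput:
    time: float
    hand: str = "none"           # rock | paper | scissors | none
    position: tuple[float, float] = (0.0, 2.0)
    moving: bool = False
    waving: bool = False
    smiling: bool = False

    def __post_init__(self) -> None:
        if self.hand not in HANDS and self.hand != "none":
            raise ValueError(f"invalid hand {self.hand!r}")
        x, y = self.position
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError("user position must be finite")


def agent_hand_choice(rng: np.random.Generator) -> str:
    """Uniform random choice among the three hands."""
    return HANDS[int(rng.integers(3))]


def judge_round(agent_hand: str, user_hand: str) -> RoundOutcome:
    """Standard dominance: rock > scissors > paper > rock."""
    for hand in (agent_hand, user_hand):
        if hand not in HANDS:
            raise ValueError(f"cannot judge a round with hand {hand!r}")
    if agent_hand == user_hand:
        return RoundOutcome.DRAW
    return RoundOutcome.AGENT_WIN if _BEATS[agent_hand] == user_hand else RoundOutcome.USER_WIN


def gaze_request(event: GazeEvent, priority: Priority) -> BehaviourRequest:
    actuators = {"eyes", "head"} if event.head_rotation > 0 else {"eyes"}
    return BehaviourRequest(
        modality=Modality.GAZE, actuators=frozenset(actuators), priority=priority,
        requested_onset=event.time, duration=event.duration, payload=event,
    )


def gesture_request(event: GestureEvent, priority: Priority) -> BehaviourRequest:
    modality = Modality.POSTURE if event.kind in ("posture_shift", "lean_set") else Modality.GESTURE
    return BehaviourRequest(
        modality=modality, actuators=event.actuators, priority=priority,
        requested_onset=event.time, duration=event.duration, payload=event,
    )


class RPSInteraction:
    """The rock-paper-scissors session state machine.

    ``step`` is called once per simulation tick with the current user
    input; it returns the (possibly new) state, the game events raised
    this tick, and any communicative behaviour requests.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        rounds: int = 5,
        dwell: dict | None = None,
        gesture_params: GestureParams | None = None,
        head_speed: float = 70.0,
    ):
        if rounds <= 0:
            raise ValueError("rounds must be positive")
        self.rng = rng
        self.rounds = rounds
        self.dwell = dict(DEFAULT_DWELL, **(dwell or {}))
        self.gesture_params = gesture_params
        self.head_speed = head_speed
        self.state = GameState.READY
        self.entered = 0.0
        self.round_index = 0
        self.agent_hand: str | None = None
        self.user_hand: str | None = None
        self.wins = {"agent": 0, "user": 0, "draw": 0}
        self.missed_rounds = 0

    def _dwell_done(self, clock: float) -> bool:
        return clock - self.entered >= self.dwell[self.state.value]

    def _goto(self, state: GameState, clock: float) -> None:
        self.state = state
        self.entered = clock

    def step(self, user: UserInput, clock: float):
        events: list[dict] = []
        requests: list[BehaviourRequest] = []
        state = self.state

        if state is GameState.READY:
            # anticipation builds every tick spent approaching "Go"
            events.append({"event": "approach_go", "time": clock})
            if self._dwell_done(clock) and not user.moving:
                self._goto(GameState.GO, clock)

        elif state is GameState.GO:
            if self._dwell_done(clock):
                self.agent_hand = agent_hand_choice(self.rng)
                hand_ev = communicative_gesture(self.agent_hand, self.gesture_params, time=clock)
                requests.append(gesture_request(hand_ev, Priority.HIGH))
                # right after playing, glance at what the user played
                look = communicative_gaze("user_hand", time=clock, head_speed=self.head_speed)
                requests.append(gaze_request(look, Priority.MID))
                events.append({"event": "agent_play_hand", "time": clock,
                               "hand": self.agent_hand})
                self.user_hand = None
                self._goto(GameState.HANDS, clock)

        elif state is GameState.HANDS:
            if user.hand != "none":
                self.user_hand = user.hand
            if self._dwell_done(clock):
                self._judge(events, requests, clock)
                self._goto(GameState.RESULT, clock)

        elif state is GameState.RESULT:
            if self._dwell_done(clock):
                if self.round_index < self.rounds:
                    self._goto(GameState.READY, clock)
                else:
                    self._goto(GameState.WAIT, clock)

        # WAIT is terminal idling; unknown conditions leave the state unchanged
        return self.state, events, requests

    def _judge(self, events: list, requests: list, clock: float) -> None:
        self.round_index += 1
        if self.user_hand is None:
            self.missed_rounds += 1
            events.append({"event": "missed_round", "time": clock,
                           "round": self.round_index})
        else:
            outcome = judge_round(self.agent_hand, self.user_hand)
            key = {"agent_win": "agent", "user_win": "user", "draw": "draw"}[outcome.value]
            self.wins[key] += 1
            game_event = {"agent_win": "agent_win", "user_win": "agent_lose",
                          "draw": "draw"}[outcome.value]
            events.append({"event": game_event, "time": clock,
                           "round": self.round_index,
                           "agent_hand": self.agent_hand,
                           "user_hand": self.user_hand})
        events.append({"event": "result", "time": clock, "round": self.round_index})
        events.append({"event": "cycle_repeat", "time": clock, "round": self.round_index})
        events.append({"event": "enter_wait", "time": clock})
        # confirm the tally on the scoreboard
        look = communicative_gaze("gui", time=clock, head_speed=self.head_speed)
        requests.append(gaze_request(look, Priority.MID))


def fsm_step(machine: RPSInteraction, user: UserInput, clock: float):
    """Functional alias for one machine step."""
    return machine.step(user, clock)
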