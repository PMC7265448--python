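"""Observer ethogram and the 0-4 startle magnitude ground-truth scheme.

Human observers code slow-motion video of each test against a fixed
ethogram.  The Observer Startle Magnitude score is the rank of the
strongest reaction seen:

====  =========================================================
4     Flee (rapid exit from the pen)
3     Jump and fall, Jump away
2     Jump on spot, Spin to face
1     Side step, Head up, Head turn, Muscle ripple, Ear prick
0     no startle reaction
====  =========================================================

Observer Freeze Duration is the summed duration of coded Freeze events;
freezes shorter than 0.4 s are re-classified as "no freeze" because they
lack the sustained tension/immobility of the behavioural definition
(a freeze of exactly 0.4 s is retained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = ["BehaviourCode", "BehaviourEvent", "ObserverRecord",
           "score_startle", "total_freeze_duration", "SCORE_OF_CODE"]


class BehaviourCode(str, Enum):
    JUMP_AND_FALL = "JumpAndFall"
    JUMP_AWAY = "JumpAway"
    JUMP_ON_SPOT = "JumpOnSpot"
    SPIN_TO_FACE = "SpinToFace"
    SIDE_STEP = "SideStep"
    HEAD_UP = "HeadUp"
    HEAD_TURN = "HeadTurn"
    MUSCLE_RIPPLE = "MuscleRipple"
    EAR_PRICK = "EarPrick"
    SNIFF_APPROACH = "SniffApproach"
    FREEZE = "Freeze"
    FLEE = "Flee"
    SLOWLY_LEAVE = "SlowlyLeave"
    RETURN_TO_NORMAL = "ReturnToNormal"


#: startle score contributed by each code; codes absent here (Freeze,
#: SniffApproach and the outcome behaviours) do not contribute.
SCORE_OF_CODE: dict[BehaviourCode, int] = {
    BehaviourCode.FLEE: 4,
    BehaviourCode.JUMP_AND_FALL: 3,
    BehaviourCode.JUMP_AWAY: 3,
    BehaviourCode.JUMP_ON_SPOT: 2,
    BehaviourCode.SPIN_TO_FACE: 2,
    BehaviourCode.SIDE_STEP: 1,
    BehaviourCode.HEAD_UP: 1,
    BehaviourCode.HEAD_TURN: 1,
    BehaviourCode.MUSCLE_RIPPLE: 1,
    BehaviourCode.EAR_PRICK: 1,
}

MIN_FREEZE_S = 0.4


@dataclass(frozen=True)
class BehaviourEvent:
    """One coded behaviour with its time span, seconds from stimulus."""

    code: BehaviourCode
    start_s: float = 0.0
    end_s: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.start_s <= self.end_s <= 30:
            raise ValueError("need 0 <= start_s <= end_s <= 30")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def score_startle(events: Iterable[BehaviourEvent]) -> int:
    """Startle magnitude score 0-4: the strongest reaction present."""
    return max((SCORE_OF_CODE.get(e.code, 0) for e in events), default=0)


def total_freeze_duration(events: Iterable[BehaviourEvent],
                          min_freeze_s: float = MIN_FREEZE_S) -> float:
    """Summed duration of Freeze events of at least ``min_freeze_s``.

    Shorter freezes are re-classified as no freeze; the boundary value is
    retained (only strictly shorter events are dropped).
    """
    return sum(e.duration_s for e in events
               if e.code is BehaviourCode.FREEZE
               and e.duration_s >= min_freeze_s)


@dataclass
class ObserverRecord:
    """Coded events of one test plus the derived ground-truth measures."""

    events: list[BehaviourEvent] = field(default_factory=list)
    test_id: str = ""

    @property
    def startle_score(self) -> int:
        return score_startle(self.events)

    @property
    def freeze_duration_s(self) -> float:
        return total_freeze_duration(self.events)
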