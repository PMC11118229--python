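"""Shared vocabulary of the bilateral gait recognizer.

This module defines the finite label sets the whole package reasons over —
seven walking activities, eight gait events, and their Cartesian product of
56 (activity, event) class pairs — together with the gait-phase geometry of
one cycle and the two bilateral sequential-relationship tables used by the
cross-limb elimination rules:

* the *activity pair table*: which (right activity, left activity)
  combinations can co-occur during level walking (23 pairs), and
* the *event pair table*: which (right event, left event) combinations can
  co-occur given the half-cycle offset between the limbs (16 pairs).

Activities split into three steady modes — linear walking (LW), clockwise
circular walking (CW) and counterclockwise circular walking (CCW) — and four
transition modes, each a single transitional gait cycle between two steady
modes: LC (LW→CW), LCC (LW→CCW), CL (CW→LW) and CCL (CCW→LW).

Both tables are stored as literal data (the integer codes are the single
source of truth) and can be round-tripped through YAML so variants can be
configured without touching code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, NamedTuple, Tuple

import numpy as np
import yaml

__all__ = [
    "WalkingActivity",
    "GaitEvent",
    "ClassPair",
    "ALL_CLASS_PAIRS",
    "PairTable",
    "ACTIVITY_PAIR_TABLE",
    "EVENT_PAIR_TABLE",
    "PHASE_BOUNDS",
    "next_event",
    "activity_pair_allowed",
    "event_pair_allowed",
    "upcoming_activity",
    "event_at_phase",
]


class WalkingActivity(enum.IntEnum):
    """The seven walking activities, coded 1-7.

    LW/CW/CCW are steady; LC/LCC/CL/CCL are single-cycle transitions.
    """

    LW = 1   # linear walking
    CW = 2   # clockwise circular walking
    CCW = 3  # counterclockwise circular walking
    LC = 4   # LW -> CW transition
    LCC = 5  # LW -> CCW transition
    CL = 6   # CW -> LW transition
    CCL = 7  # CCW -> LW transition

    @property
    def is_steady(self) -> bool:
        return self.value <= 3

    @property
    def is_transition(self) -> bool:
        return self.value >= 4


class GaitEvent(enum.IntEnum):
    """The eight gait events of one cycle, cyclically ordered 1→2→…→8→1."""

    IC = 1   # initial contact
    LR = 2   # loading response
    MSt = 3  # mid-stance
    TSt = 4  # terminal stance
    PS = 5   # pre-swing
    IS = 6   # initial swing
    MSw = 7  # mid-swing
    TSw = 8  # terminal swing


class ClassPair(NamedTuple):
    """One (walking activity, gait event) hypothesis."""

    activity: WalkingActivity
    event: GaitEvent


#: All 56 class pairs in (activity-major, event-minor) order.  Array-based
#: code throughout the package indexes posteriors and likelihoods by position
#: in this tuple.
ALL_CLASS_PAIRS: Tuple[ClassPair, ...] = tuple(
    ClassPair(a, e) for a in WalkingActivity for e in GaitEvent
)

#: Integer activity / event codes aligned with ``ALL_CLASS_PAIRS``.
CLASS_ACTIVITY_CODES: np.ndarray = np.array([p.activity for p in ALL_CLASS_PAIRS])
CLASS_EVENT_CODES: np.ndarray = np.array([p.event for p in ALL_CLASS_PAIRS])

CLASS_INDEX: Dict[ClassPair, int] = {p: i for i, p in enumerate(ALL_CLASS_PAIRS)}


def next_event(event: GaitEvent | int) -> GaitEvent:
    """Cyclic successor of a gait event (…→TSw→IC→LR→…)."""
    return GaitEvent(int(event) % 8 + 1)


# ---------------------------------------------------------------------------
# Bilateral sequential-relationship tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairTable:
    """A set of allowed (right code, left code) pairs.

    Queried directly for right-side elimination and transposed for left-side
    elimination.
    """

    allowed: frozenset

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, Iterable[int]]) -> "PairTable":
        pairs = frozenset(
            (int(r), int(l)) for r, lefts in mapping.items() for l in lefts
        )
        return cls(pairs)

    def __contains__(self, pair: Tuple[int, int]) -> bool:
        return (int(pair[0]), int(pair[1])) in self.allowed

    def __len__(self) -> int:
        return len(self.allowed)

    def contains(self, right: int, left: int) -> bool:
        return (int(right), int(left)) in self.allowed

    def left_partners(self, right: int) -> frozenset:
        return frozenset(l for r, l in self.allowed if r == int(right))

    def transposed(self) -> "PairTable":
        return PairTable(frozenset((l, r) for r, l in self.allowed))

    def as_bool_matrix(self, n: int) -> np.ndarray:
        """(n, n) boolean matrix, [right-1, left-1] = allowed."""
        m = np.zeros((n, n), dtype=bool)
        for r, l in self.allowed:
            m[r - 1, l - 1] = True
        return m

    def to_mapping(self) -> Dict[int, list]:
        out: Dict[int, list] = {}
        for r, l in sorted(self.allowed):
            out.setdefault(r, []).append(l)
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PairTable":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))


#: Allowed (right activity, left activity) pairs during level walking.
#: 23 pairs; rows keyed by the right limb's activity code.
ACTIVITY_PAIR_TABLE = PairTable.from_mapping(
    {
        1: [1, 4, 5, 6, 7],
        2: [2, 4, 6],
        3: [3, 5, 7],
        4: [1, 2, 4],
        5: [1, 3, 5],
        6: [1, 2, 6],
        7: [1, 3, 7],
    }
)

#: Allowed (right event, left event) pairs given the half-cycle bilateral
#: offset.  16 pairs; the relation is symmetric.
EVENT_PAIR_TABLE = PairTable.from_mapping(
    {
        1: [5],
        2: [5, 6],
        3: [6, 7],
        4: [7, 8],
        5: [1, 2, 8],
        6: [2, 3],
        7: [3, 4],
        8: [4, 5],
    }
)


def activity_pair_allowed(
    right: WalkingActivity | int,
    left: WalkingActivity | int,
    table: PairTable = ACTIVITY_PAIR_TABLE,
) -> bool:
    """True iff the (right, left) activity pair can co-occur."""
    return table.contains(int(right), int(left))


def event_pair_allowed(
    right: GaitEvent | int,
    left: GaitEvent | int,
    table: PairTable = EVENT_PAIR_TABLE,
) -> bool:
    """True iff the (right, left) gait-event pair can co-occur."""
    return table.contains(int(right), int(left))


# ---------------------------------------------------------------------------
# Gait-phase geometry
# ---------------------------------------------------------------------------

#: Half-open [start, end) cycle-fraction bounds of each gait event.  The
#: bounds partition [0, 1).  The ends are the complements of the transition
#: prediction delay factors (an event's remaining-cycle fraction at its end);
#: the split of the combined first 10% between IC and LR follows standard
#: gait-phase proportions (IC ≈ first 2% of the cycle).
PHASE_BOUNDS: Dict[GaitEvent, Tuple[float, float]] = {
    GaitEvent.IC: (0.00, 0.02),
    GaitEvent.LR: (0.02, 0.10),
    GaitEvent.MSt: (0.10, 0.30),
    GaitEvent.TSt: (0.30, 0.50),
    GaitEvent.PS: (0.50, 0.60),
    GaitEvent.IS: (0.60, 0.73),
    GaitEvent.MSw: (0.73, 0.87),
    GaitEvent.TSw: (0.87, 1.00),
}

_PHASE_STARTS = np.array([PHASE_BOUNDS[GaitEvent(c)][0] for c in range(1, 9)])


def event_at_phase(phase):
    """Gait-event code(s) at cycle fraction ``phase`` (wrapped into [0, 1)).

    Accepts a scalar or an array; returns int code(s) 1-8.
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    codes = np.searchsorted(_PHASE_STARTS, phase, side="right")
    if codes.ndim == 0:
        return int(codes)
    return codes.astype(np.int64)


# ---------------------------------------------------------------------------
# Transition -> upcoming steady activity
# ---------------------------------------------------------------------------

_UPCOMING = {
    WalkingActivity.LC: WalkingActivity.CW,
    WalkingActivity.LCC: WalkingActivity.CCW,
    WalkingActivity.CL: WalkingActivity.LW,
    WalkingActivity.CCL: WalkingActivity.LW,
}


def upcoming_activity(transition: WalkingActivity | int) -> WalkingActivity:
    """Steady activity that follows a transition activity.

    Raises ``ValueError`` for a steady-activity input.
    """
    transition = WalkingActivity(int(transition))
    if transition not in _UPCOMING:
        raise ValueError(
            f"{transition.name} is a steady activity, not a transition"
        )
    return _UPCOMING[transition]
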