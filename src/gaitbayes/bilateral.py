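"""Bilateral elimination rules 2 and 3 (cross-limb pruning).

The two limbs exchange their post-rule-1 potential sets at every sample.
Rule 2 keeps a class on one side only if some potential activity on the other
side licenses its activity under the bilateral activity-pair table; rule 3
does the same for gait events under the event-pair table, after rule 2.  The
quantifier is existential: a class survives if ANY partner on the other side
licenses it, the only reading that never deletes jointly consistent truths.
Left-side queries use the transposed tables (the pair tables are stated for
the right side).  Updates within a rule are simultaneous (both sides judged
against the other side's pre-rule set) and fail-open: a rule that would
empty a side's class set is skipped for that side.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import FrozenSet

import numpy as np

from .core import ACTIVITY_PAIR_TABLE, EVENT_PAIR_TABLE, PairTable
from .fc_besis import PosteriorState, _restrict

__all__ = ["BilateralState", "eliminate_rule2", "eliminate_rule3", "apply_bers"]


@dataclass(frozen=True)
class BilateralState:
    """The two limbs' posterior states plus their projected potential sets."""

    right: PosteriorState
    left: PosteriorState

    @property
    def rpwa(self) -> FrozenSet[int]:
        return self.right.activities

    @property
    def lpwa(self) -> FrozenSet[int]:
        return self.left.activities

    @property
    def rpge(self) -> FrozenSet[int]:
        return self.right.events

    @property
    def lpge(self) -> FrozenSet[int]:
        return self.left.events


def pair_survival_mask(own_codes, other_codes, table: PairTable, side: str) -> np.ndarray:
    """Mask over ``own_codes``: code has >= 1 partner in ``other_codes``.

    ``table`` is keyed (right, left); for the left side the transposed query
    is used.
    """
    other = set(int(c) for c in other_codes)
    if side == "right":
        ok = {r for r, l in table.allowed if l in other}
    elif side == "left":
        ok = {l for r, l in table.allowed if r in other}
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return np.array([int(c) in ok for c in own_codes], dtype=bool)


def _eliminate_by_codes(state: BilateralState, table: PairTable, attr: str) -> BilateralState:
    r_codes = np.array([int(getattr(p, attr)) for p in state.right.classes])
    l_codes = np.array([int(getattr(p, attr)) for p in state.left.classes])
    keep_r = pair_survival_mask(r_codes, l_codes, table, side="right")
    keep_l = pair_survival_mask(l_codes, r_codes, table, side="left")
    return replace(
        state,
        right=_restrict(state.right, keep_r),
        left=_restrict(state.left, keep_l),
    )


def eliminate_rule2(
    state: BilateralState, table: PairTable = ACTIVITY_PAIR_TABLE
) -> BilateralState:
    """Cross-limb activity pruning (elimination rule 2)."""
    return _eliminate_by_codes(state, table, "activity")


def eliminate_rule3(
    state: BilateralState, table: PairTable = EVENT_PAIR_TABLE
) -> BilateralState:
    """Cross-limb gait-event pruning (elimination rule 3); applied after rule 2."""
    return _eliminate_by_codes(state, table, "event")


def apply_bers(
    state: BilateralState,
    activity_table: PairTable = ACTIVITY_PAIR_TABLE,
    event_table: PairTable = EVENT_PAIR_TABLE,
) -> BilateralState:
    """Rule 2 then rule 3, synchronously for one sample."""
    return eliminate_rule3(eliminate_rule2(state, activity_table), event_table)
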