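"""Transition prediction: timing of the upcoming steady activity's first HC.

Once a transition walking activity (LC, LCC, CL, CCL) is recognized, the
first heel contact (HC) of the upcoming steady activity is predicted from the
recognized gait event and the mean gait cycle time (MGCT, mean duration of
the last three completed cycles).  Because each gait event occupies a fixed
fraction of a normal level-walking cycle, the delay from the event to the end
of the transition cycle is a fixed fraction of MGCT:

    event        IC/LR  MSt  TSt  PS   IS    MSw   TSw
    delay factor 0.9    0.7  0.5  0.4  0.27  0.13  <=0.13 (upper bound)

The TSw case only bounds the delay from above (the HC occurs *within*
0.13 * MGCT); its prediction carries ``is_upper_bound=True`` and evaluation
should treat it as a bound, not a point estimate.  The factor is applied
from the moment of recognition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .core import GaitEvent, WalkingActivity, upcoming_activity

__all__ = [
    "TRANSITION_FACTORS",
    "GaitCycleClock",
    "TransitionPrediction",
    "compute_mgct",
    "predict",
    "predictions_to_frame",
]

#: Delay from recognition to the upcoming steady activity's first HC, as a
#: fraction of MGCT, by recognized gait event.
TRANSITION_FACTORS: Dict[GaitEvent, float] = {
    GaitEvent.IC: 0.9,
    GaitEvent.LR: 0.9,
    GaitEvent.MSt: 0.7,
    GaitEvent.TSt: 0.5,
    GaitEvent.PS: 0.4,
    GaitEvent.IS: 0.27,
    GaitEvent.MSw: 0.13,
    GaitEvent.TSw: 0.13,  # upper bound: HC within 0.13 * MGCT
}

#: Events whose factor is an upper bound rather than a point estimate.
UPPER_BOUND_EVENTS = frozenset({GaitEvent.TSw})


class GaitCycleClock:
    """Per-limb record of IC onsets; supplies the mean gait cycle time."""

    def __init__(self):
        self.ic_onsets: List[float] = []

    def add_ic(self, t: float) -> None:
        if self.ic_onsets and t <= self.ic_onsets[-1]:
            raise ValueError("IC onsets must be strictly increasing")
        self.ic_onsets.append(float(t))

    @property
    def n_onsets(self) -> int:
        return len(self.ic_onsets)

    def mgct(self) -> float:
        """Mean duration of the last min(3, available) completed cycles."""
        if self.n_onsets < 2:
            raise ValueError("need at least 2 IC onsets to compute MGCT")
        durations = np.diff(self.ic_onsets[-4:])
        return float(durations[-3:].mean())


def compute_mgct(clock: GaitCycleClock) -> float:
    """Mean gait cycle time of the clock's last three completed cycles."""
    return clock.mgct()


@dataclass(frozen=True)
class TransitionPrediction:
    """One prediction of the upcoming steady activity and its first HC."""

    issued_at: float                 # s
    transition: WalkingActivity      # recognized transition activity
    event: GaitEvent                 # recognized gait event at issue time
    upcoming: WalkingActivity        # predicted upcoming steady activity
    factor: float                    # delay factor applied
    mgct: float                      # s
    predicted_hc: float              # s, absolute
    is_upper_bound: bool             # True for the TSw ("within") case

    def __post_init__(self):
        if self.predicted_hc < self.issued_at:
            raise ValueError("predicted HC time must not precede issue time")


def predict(
    transition: WalkingActivity | int,
    event: GaitEvent | int,
    mgct: float,
    now: float,
) -> TransitionPrediction:
    """Predict the first HC of the upcoming steady activity.

    Raises ``ValueError`` if ``transition`` is a steady activity (the module
    is skipped outside transitions) or ``mgct`` is not positive.
    """
    transition = WalkingActivity(int(transition))
    event = GaitEvent(int(event))
    if not transition.is_transition:
        raise ValueError(
            f"{transition.name} is steady: transition prediction module skipped"
        )
    if mgct <= 0:
        raise ValueError("mgct must be positive")
    factor = TRANSITION_FACTORS[event]
    return TransitionPrediction(
        issued_at=float(now),
        transition=transition,
        event=event,
        upcoming=upcoming_activity(transition),
        factor=factor,
        mgct=float(mgct),
        predicted_hc=float(now) + factor * float(mgct),
        is_upper_bound=event in UPPER_BOUND_EVENTS,
    )


def predictions_to_frame(predictions) -> pd.DataFrame:
    """Tabulate prediction records for CSV export."""
    rows = []
    for p in predictions:
        side = None
        if isinstance(p, tuple):  # (side, prediction)
            side, p = p
        rows.append(
            {
                "side": side,
                "issued_at": p.issued_at,
                "transition": int(p.transition),
                "event": int(p.event),
                "factor": p.factor,
                "mgct": p.mgct,
                "predicted_hc": p.predicted_hc,
                "upcoming": int(p.upcoming),
                "is_upper_bound": p.is_upper_bound,
            }
        )
    return pd.DataFrame(rows)
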