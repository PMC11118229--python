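"""Unilateral finite-class recursive Bayesian engine.

State is an explicit posterior over a finite, shrinking-and-recovering set of
(activity, event) class pairs V_t.  Each sample applies

    P(g_m | s_t) = P(s_t | g_m) P(g_m | s_{t-1}) / P(s_t | s_{t-1}),

with the normalizer P(s_t | s_{t-1}) = sum_m P(s_t | g_m) P(g_m | s_{t-1}).
Elimination rule 1 prunes V_t from within-limb evidence: (a) classes whose
observation likelihood falls below ``tau1`` times the current maximum, and
(b) once a gait event has been confidently recognized, classes whose event is
neither the recognized event nor its cyclic successor (the only temporally
admissible options within one limb).  Both parts can be disabled; a rule that
would empty V_t is skipped (fail-open).  Activity and event recognitions are
the argmax of the corresponding marginal posterior, declared only when its
mass reaches the confidence threshold theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import ClassPair, GaitEvent, WalkingActivity, next_event

__all__ = [
    "PosteriorState",
    "Decision",
    "init_prior",
    "step",
    "eliminate_rule1",
    "marginals",
    "decide",
    "likelihood_ratio_mask",
    "event_admissible_mask",
    "advance_event_prior",
]

logger = logging.getLogger(__name__)

#: Default per-surviving-class prior mass floor.  It prevents absorbing
#: zeros and bounds the evidence needed to revise an entrenched hypothesis
#: (about log(theta / MASS_FLOOR) nats of geometric-mean log-likelihood).
MASS_FLOOR = 1e-3


@dataclass(frozen=True)
class PosteriorState:
    """Posterior mass over the surviving finite class set at one sample."""

    classes: Tuple[ClassPair, ...]  # V_t
    probs: np.ndarray               # aligned with classes, sums to 1
    normalizer: float = 1.0         # P(s_t | s_{t-1}) of the last update
    t: int = 0

    def __post_init__(self):
        if len(self.classes) == 0:
            raise ValueError("finite class set V_t must be non-empty")
        if len(self.classes) != len(self.probs):
            raise ValueError("classes and probs must align")

    @property
    def activities(self) -> frozenset:
        """Potential walking activities projected from V_t."""
        return frozenset(int(p.activity) for p in self.classes)

    @property
    def events(self) -> frozenset:
        """Potential gait events projected from V_t."""
        return frozenset(int(p.event) for p in self.classes)


@dataclass(frozen=True)
class Decision:
    """A thresholded recognition; ``None`` marks undecided."""

    activity: Optional[WalkingActivity]
    event: Optional[GaitEvent]
    latency_ms: Optional[float] = None


def init_prior(classes: Sequence[ClassPair]) -> PosteriorState:
    """Uniform prior 1/M over M classes."""
    classes = tuple(classes)
    if not classes:
        raise ValueError("cannot build a prior over an empty class set")
    M = len(classes)
    return PosteriorState(classes=classes, probs=np.full(M, 1.0 / M), t=0)


def step(state: PosteriorState, s, model) -> PosteriorState:
    """One Bayesian update of the posterior with observation ``s``.

    Likelihoods come from ``model`` (a fitted
    :class:`~gaitbayes.likelihood.HistogramLikelihoodModel`).  If the
    normalizer vanishes the posterior resets to uniform over V_t (logged).
    """
    lik = np.array([model.observation_likelihood(s, m) for m in state.classes])
    return update_with_likelihoods(state, lik)


def update_with_likelihoods(state: PosteriorState, lik: np.ndarray) -> PosteriorState:
    """Bayes update of ``state`` with precomputed per-class likelihoods."""
    lik = np.asarray(lik, dtype=float)
    post = lik * state.probs
    normalizer = float(post.sum())
    if normalizer <= 0.0:
        logger.warning("zero normalizer at t=%d; resetting to uniform over V_t", state.t)
        post = np.full(len(state.classes), 1.0 / len(state.classes))
    else:
        post = post / normalizer
    return PosteriorState(
        classes=state.classes, probs=post, normalizer=normalizer, t=state.t + 1
    )


def advance_event_prior(post: np.ndarray, hazard: float) -> np.ndarray:
    """Gait-event progression step of the prior (per-sample dynamics).

    Moves fraction ``hazard`` of every class's mass to the class with the
    same activity and the successor event.  With hazard h the expected dwell
    time in an event is 1/h samples, matching the order of real event
    durations at 100 Hz; without this term the static-prior recursion cannot
    revise an entrenched event hypothesis within a short event's window.
    ``post`` must be ordered so that equal-activity classes hold their eight
    events contiguously in cyclic order (the :data:`ALL_CLASS_PAIRS` layout).
    """
    if not 0 <= hazard < 1:
        raise ValueError("hazard must lie in [0, 1)")
    if hazard == 0:
        return post
    post = np.asarray(post, dtype=float).reshape(-1, 8)
    return ((1.0 - hazard) * post + hazard * np.roll(post, 1, axis=1)).ravel()


def likelihood_ratio_mask(likelihoods: np.ndarray, tau1: float) -> np.ndarray:
    """Boolean mask of classes with likelihood >= tau1 * max likelihood."""
    lik = np.asarray(likelihoods, dtype=float)
    return lik >= tau1 * lik.max()


def event_admissible_mask(event_codes: np.ndarray, current: GaitEvent | int) -> np.ndarray:
    """Mask of classes whose event is the current event or its successor."""
    current = int(current)
    succ = int(next_event(current))
    codes = np.asarray(event_codes)
    return (codes == current) | (codes == succ)


def eliminate_rule1(
    state: PosteriorState,
    likelihoods: np.ndarray,
    current_event: Optional[GaitEvent | int] = None,
    tau1: float = 0.01,
    use_ratio: bool = True,
    use_event: bool = True,
) -> PosteriorState:
    """Within-limb pruning of V_t (elimination rule 1).

    ``likelihoods`` aligns with ``state.classes``.  Survivors must pass the
    likelihood-ratio test at ``tau1`` and, when a recognized event is given,
    the temporal admissibility test.  If the combined rule would empty V_t
    the event part is dropped (fail-open; the ratio part alone can never
    empty the set because the maximizer always survives).
    """
    if not 0 < tau1 <= 1:
        raise ValueError("tau1 must lie in (0, 1]")
    lik = np.asarray(likelihoods, dtype=float)
    keep = np.ones(len(state.classes), dtype=bool)
    if use_ratio:
        keep &= likelihood_ratio_mask(lik, tau1)
    if use_event and current_event is not None:
        codes = np.array([int(p.event) for p in state.classes])
        combined = keep & event_admissible_mask(codes, current_event)
        if combined.any():
            keep = combined
        else:
            logger.debug(
                "rule 1 event part would empty V_t at t=%d; skipped", state.t
            )
    if keep.all():
        return state
    return _restrict(state, keep)


def _restrict(state: PosteriorState, keep: np.ndarray) -> PosteriorState:
    """Restrict V_t to ``keep`` and renormalize (fail-open on empty)."""
    if not keep.any():
        logger.debug("elimination would empty V_t at t=%d; skipped", state.t)
        return state
    classes = tuple(c for c, k in zip(state.classes, keep) if k)
    probs = state.probs[keep]
    total = probs.sum()
    probs = probs / total if total > 0 else np.full(len(classes), 1.0 / len(classes))
    return replace(state, classes=classes, probs=probs)


def marginals(state: PosteriorState) -> Tuple[np.ndarray, np.ndarray]:
    """Activity and event marginal posteriors.

    Returns ``(activity_mass, event_mass)`` of shapes (7,) and (8,), indexed
    by code - 1; classes absent from V_t contribute zero mass.
    """
    act = np.zeros(7)
    evt = np.zeros(8)
    for pair, p in zip(state.classes, state.probs):
        act[int(pair.activity) - 1] += p
        evt[int(pair.event) - 1] += p
    return act, evt


def decide(
    state: PosteriorState,
    theta: float = 0.9,
    samples_since_onset: Optional[int] = None,
    fs: float = 100.0,
) -> Decision:
    """Thresholded argmax decision on both marginals.

    An activity (event) is recognized when its marginal mass reaches
    ``theta``; ties break toward the lowest code (argmax returns the first
    maximum).  ``samples_since_onset`` converts to a decision latency in ms.
    """
    if not 0.5 < theta <= 1.0:
        raise ValueError("theta must lie in (0.5, 1]")
    act, evt = marginals(state)
    a_idx = int(np.argmax(act))
    e_idx = int(np.argmax(evt))
    activity = WalkingActivity(a_idx + 1) if act[a_idx] >= theta else None
    event = GaitEvent(e_idx + 1) if evt[e_idx] >= theta else None
    latency = None
    if samples_since_onset is not None:
        latency = samples_since_onset * 1000.0 / fs
    return Decision(activity=activity, event=event, latency_ms=latency)
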