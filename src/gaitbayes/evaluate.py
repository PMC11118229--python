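"""Streaming replay of the recognizer and the evaluation metrics.

``replay`` runs both limbs' finite-class Bayesian recognizers over a labeled
dataset, sample by sample, in one of two modes: ``"fc"`` (within-limb
elimination only) or ``"ber-fc"`` (additionally coupling the limbs through
the bilateral elimination rules).  It records per-sample thresholded and
forced-MAP decisions, surviving-class counts, and the transition predictions
issued along the way.

Metrics mirror the method's evaluation protocol: confusion matrices and
accuracies at segment level (one majority verdict per labeled activity
segment) and sample level, decision latencies from segment onset, the mean
surviving-class count per system, and a timing report per transition
prediction — MPT (real HC minus issue time) and MTD (real HC minus predicted
HC; positive means the prediction was early).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    ACTIVITY_PAIR_TABLE,
    ALL_CLASS_PAIRS,
    CLASS_ACTIVITY_CODES,
    CLASS_EVENT_CODES,
    EVENT_PAIR_TABLE,
    GaitEvent,
    WalkingActivity,
)
from .bilateral import pair_survival_mask
from .fc_besis import advance_event_prior, event_admissible_mask, likelihood_ratio_mask
from .likelihood import HistogramLikelihoodModel
from .preprocess import assemble_features, lowpass_frames
from .simulator import GaitDataset, ic_onset_times
from .transition import GaitCycleClock, TransitionPrediction, predict

__all__ = [
    "ReplayConfig",
    "ReplayResult",
    "ConfusionMatrix",
    "TimingReport",
    "train_models",
    "replay",
    "segments",
    "segment_verdicts",
    "confusion",
    "accuracy",
    "macro_recall",
    "class_count_stats",
    "decision_latencies",
    "timing_report",
]

SIDES = ("right", "left")


@dataclass(frozen=True)
class ReplayConfig:
    """Every tunable of a replay run (defaults are the package defaults)."""

    tau1: float = 0.01            # rule-1 likelihood-ratio threshold
    theta: float = 0.9            # decision confidence threshold
    mass_floor: float = 1e-3      # prior mass floor per surviving class
    event_hazard: float = 0.15    # per-sample event-progression hazard
    use_rule1_ratio: bool = True
    use_rule1_event: bool = True
    fs: float = 100.0
    filter_input: bool = True     # 6 Hz Butterworth before recognition
    filter_fc: float = 6.0
    filter_order: int = 2
    reissue_on_event_change: bool = False


def _prepare_features(dataset: GaitDataset, config: ReplayConfig) -> Dict[str, np.ndarray]:
    # datasets may supply their own per-side feature extraction (estimator path)
    custom = getattr(dataset, "features", None)
    if callable(custom):
        return {side: custom(side) for side in SIDES}
    frames = dataset.frames
    if config.filter_input:
        frames = lowpass_frames(
            frames, fs=config.fs, fc=config.filter_fc, order=config.filter_order
        )
    return {side: assemble_features(frames, side)[0] for side in SIDES}


def train_models(
    dataset: GaitDataset,
    n_bins: int = 20,
    alpha: float = 1.0,
    config: Optional[ReplayConfig] = None,
) -> Dict[str, HistogramLikelihoodModel]:
    """Fit one histogram likelihood model per limb from a labeled dataset."""
    config = config or ReplayConfig()
    feats = _prepare_features(dataset, config)
    models = {}
    for side in SIDES:
        models[side] = HistogramLikelihoodModel(n_bins=n_bins, alpha=alpha).fit(
            feats[side], dataset.label_codes(side)
        )
    return models


@dataclass
class ReplayResult:
    """Per-sample outputs of one replay run."""

    times: np.ndarray
    mode: str
    config: ReplayConfig
    #: thresholded decisions per side, (n, 2) codes; 0 = undecided
    decisions: Dict[str, np.ndarray]
    #: forced argmax (MAP) decisions per side, (n, 2) codes
    map_decisions: Dict[str, np.ndarray]
    #: surviving-class count |V_t| per side after all eliminations
    class_counts: Dict[str, np.ndarray]
    #: transition predictions as (side, TransitionPrediction)
    predictions: List[Tuple[str, TransitionPrediction]] = field(default_factory=list)
    #: posterior trace per side, (n, 56), populated when requested
    posteriors: Optional[Dict[str, np.ndarray]] = None

    def class_count_frame(self) -> pd.DataFrame:
        """Per-sample diagnostic trace, CSV-exportable."""
        return pd.DataFrame(
            {
                "time": self.times,
                "right_count": self.class_counts["right"],
                "left_count": self.class_counts["left"],
            }
        )


def replay(
    dataset: GaitDataset,
    models: Dict[str, HistogramLikelihoodModel],
    mode: str = "ber-fc",
    config: Optional[ReplayConfig] = None,
    keep_posteriors: bool = False,
) -> ReplayResult:
    """Run both limbs' recognizers over a dataset, one step per sample.

    ``mode="fc"`` runs the limbs independently; ``mode="ber-fc"`` applies the
    bilateral elimination rules between rule 1 and the Bayesian update.
    Deterministic given inputs.
    """
    if mode not in ("fc", "ber-fc"):
        raise ValueError("mode must be 'fc' or 'ber-fc'")
    config = config or ReplayConfig()
    feats = _prepare_features(dataset, config)
    for side in SIDES:
        if feats[side].shape[1] != models[side].n_features_:
            raise ValueError(f"{side} model expects {models[side].n_features_} features")

    n = len(dataset)
    times = dataset.times
    M = len(ALL_CLASS_PAIRS)
    loglik = {s: models[s].log_likelihood_matrix(feats[s]) for s in SIDES}

    post = {s: np.full(M, 1.0 / M) for s in SIDES}
    # temporal-admissibility reference: the MAP event estimate.  It advances
    # whenever the restricted posterior favors the successor (a two-hypothesis
    # sequential test), while theta-gated decisions are what gets reported —
    # a brief event like IC carries too little filtered evidence to clear
    # theta within its own window, and gating the chain on theta would
    # deadlock it at the cycle wrap.
    chain_event: Dict[str, Optional[int]] = {s: None for s in SIDES}
    clocks = {s: GaitCycleClock() for s in SIDES}
    open_transition: Dict[str, Optional[int]] = {s: None for s in SIDES}

    decisions = {s: np.zeros((n, 2), dtype=np.int64) for s in SIDES}
    map_decisions = {s: np.zeros((n, 2), dtype=np.int64) for s in SIDES}
    counts = {s: np.zeros(n, dtype=np.int64) for s in SIDES}
    posteriors = {s: np.zeros((n, M)) for s in SIDES} if keep_posteriors else None
    predictions: List[Tuple[str, TransitionPrediction]] = []

    use_bers = mode == "ber-fc"

    for i in range(n):
        lik = {}
        keep = {}
        for s in SIDES:
            ll = loglik[s][i]
            lik[s] = np.exp(ll - ll.max())  # scaled; posterior unaffected
            k = np.ones(M, dtype=bool)
            if config.use_rule1_ratio:
                k &= likelihood_ratio_mask(lik[s], config.tau1)
            if config.use_rule1_event and chain_event[s] is not None:
                k2 = k & event_admissible_mask(CLASS_EVENT_CODES, chain_event[s])
                if k2.any():
                    k = k2
            keep[s] = k

        if use_bers:
            # rule 2 (activities), simultaneous across sides, fail-open
            new = {}
            for s, o in (("right", "left"), ("left", "right")):
                ok = pair_survival_mask(
                    CLASS_ACTIVITY_CODES[keep[s]],
                    np.unique(CLASS_ACTIVITY_CODES[keep[o]]),
                    ACTIVITY_PAIR_TABLE,
                    side=s,
                )
                k = keep[s].copy()
                k[np.flatnonzero(keep[s])[~ok]] = False
                new[s] = k if k.any() else keep[s]
            keep = new
            # rule 3 (events), after rule 2
            new = {}
            for s, o in (("right", "left"), ("left", "right")):
                ok = pair_survival_mask(
                    CLASS_EVENT_CODES[keep[s]],
                    np.unique(CLASS_EVENT_CODES[keep[o]]),
                    EVENT_PAIR_TABLE,
                    side=s,
                )
                k = keep[s].copy()
                k[np.flatnonzero(keep[s])[~ok]] = False
                new[s] = k if k.any() else keep[s]
            keep = new

        for s in SIDES:
            k = keep[s]
            pr = advance_event_prior(post[s], config.event_hazard)
            prior = np.where(k, np.maximum(pr, config.mass_floor), 0.0)
            prior /= prior.sum()
            p = prior * lik[s]
            tot = p.sum()
            post[s] = (k / k.sum()) if tot <= 0 else (p / tot)
            counts[s][i] = int(k.sum())
            if posteriors is not None:
                posteriors[s][i] = post[s]

            act = np.bincount(CLASS_ACTIVITY_CODES, weights=post[s], minlength=8)[1:]
            evt = np.bincount(CLASS_EVENT_CODES, weights=post[s], minlength=9)[1:]
            a_map = int(np.argmax(act)) + 1
            e_map = int(np.argmax(evt)) + 1
            map_decisions[s][i] = (a_map, e_map)
            a_dec = a_map if act[a_map - 1] >= config.theta else 0
            e_dec = e_map if evt[e_map - 1] >= config.theta else 0
            decisions[s][i] = (a_dec, e_dec)

            event_changed = e_map != chain_event[s]
            if event_changed and e_map == int(GaitEvent.IC):
                clocks[s].add_ic(times[i])
            chain_event[s] = e_map

            if a_dec:
                activity = WalkingActivity(a_dec)
                if activity.is_transition:
                    issue = open_transition[s] != a_dec or (
                        config.reissue_on_event_change and event_changed
                    )
                    if issue and clocks[s].n_onsets >= 2:
                        predictions.append(
                            (
                                s,
                                predict(
                                    activity,
                                    GaitEvent(chain_event[s]),
                                    clocks[s].mgct(),
                                    times[i],
                                ),
                            )
                        )
                    open_transition[s] = a_dec
                else:
                    open_transition[s] = None

    return ReplayResult(
        times=times,
        mode=mode,
        config=config,
        decisions=decisions,
        map_decisions=map_decisions,
        class_counts=counts,
        predictions=predictions,
        posteriors=posteriors,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def segments(codes: np.ndarray) -> List[Tuple[int, int, int]]:
    """Contiguous runs of equal codes as (start, stop, code), stop exclusive."""
    codes = np.asarray(codes)
    if codes.size == 0:
        return []
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [codes.size]])
    return [(int(a), int(b), int(codes[a])) for a, b in zip(starts, stops)]


def segment_verdicts(
    truth: np.ndarray, decided: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """One majority verdict per true segment.

    The verdict is the most frequent confident (non-zero) per-sample decision
    within the segment (ties toward the lowest code); 0 when the segment has
    no confident decisions.  Returns (true codes, verdict codes).
    """
    true_codes, verdicts = [], []
    for a, b, code in segments(truth):
        window = decided[a:b]
        window = window[window > 0]
        verdicts.append(int(np.bincount(window).argmax()) if window.size else 0)
        true_codes.append(code)
    return np.array(true_codes), np.array(verdicts)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized confusion counts over 1-based class codes."""

    counts: np.ndarray          # (K, K), rows = truth, cols = prediction
    n_undecided: int = 0        # instances with no confident verdict

    @property
    def percent(self) -> np.ndarray:
        """Row percentages (rows with no counts stay zero)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * self.counts / totals, 0.0)
        return pct


def confusion(true_codes, pred_codes, n_classes: int) -> ConfusionMatrix:
    """Confusion matrix from aligned 1-based code arrays (0 = undecided)."""
    true_codes = np.asarray(true_codes)
    pred_codes = np.asarray(pred_codes)
    if true_codes.shape != pred_codes.shape:
        raise ValueError("true and predicted code arrays must align")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    decided = pred_codes > 0
    np.add.at(counts, (true_codes[decided] - 1, pred_codes[decided] - 1), 1)
    return ConfusionMatrix(counts=counts, n_undecided=int((~decided).sum()))


def accuracy(true_codes, pred_codes) -> float:
    """Fraction of instances with a correct verdict (undecided counts wrong)."""
    true_codes = np.asarray(true_codes)
    pred_codes = np.asarray(pred_codes)
    if true_codes.size == 0:
        raise ValueError("empty code arrays")
    return float(np.mean(true_codes == pred_codes))


def macro_recall(true_codes, pred_codes, n_classes: int) -> float:
    """Balanced accuracy: mean per-class recall over classes present in truth."""
    true_codes = np.asarray(true_codes)
    pred_codes = np.asarray(pred_codes)
    recalls = []
    for c in range(1, n_classes + 1):
        mask = true_codes == c
        if mask.any():
            recalls.append(float(np.mean(pred_codes[mask] == c)))
    if not recalls:
        raise ValueError("no classes present in truth")
    return float(np.mean(recalls))


def class_count_stats(result: ReplayResult) -> Dict[str, Tuple[float, float]]:
    """(mean, sd) surviving-class count per side, plus pooled under 'both'."""
    out = {}
    pooled = []
    for s in SIDES:
        c = result.class_counts[s]
        out[s] = (float(c.mean()), float(c.std()))
        pooled.append(c)
    pooled = np.concatenate(pooled)
    out["both"] = (float(pooled.mean()), float(pooled.std()))
    return out


def decision_latencies(
    result: ReplayResult, dataset: GaitDataset, side: str, which: str = "activity"
) -> np.ndarray:
    """Per-segment latency (ms) from onset to first correct confident decision.

    Segments never correctly recognized are omitted.
    """
    col = 0 if which == "activity" else 1
    truth = dataset.label_codes(side)[:, col]
    decided = result.decisions[side][:, col]
    dt_ms = 1000.0 / result.config.fs
    out = []
    for a, b, code in segments(truth):
        hits = np.flatnonzero(decided[a:b] == code)
        if hits.size:
            out.append(hits[0] * dt_ms)
    return np.array(out)


@dataclass(frozen=True)
class TimingReport:
    """Per-prediction timing rows and their per-side aggregates."""

    table: pd.DataFrame  # side, issued_at, predicted_hc, real_hc, mpt_ms, mtd_ms, ...

    def aggregates(self) -> pd.DataFrame:
        """mean ± sd of MPT and MTD per side (point predictions only)."""
        pt = self.table[~self.table["is_upper_bound"]]
        return pt.groupby("side")[["mpt_ms", "mtd_ms"]].agg(["mean", "std", "count"])


def timing_report(result: ReplayResult, dataset: GaitDataset) -> TimingReport:
    """MPT/MTD per transition prediction against the true upcoming HC.

    The real HC is the limb's first true IC onset after the issue time whose
    activity is steady (the end of the transition cycle).  MPT = real - issue
    time; MTD = real - predicted, positive when the prediction is early.
    Raises ``ValueError`` when the run issued no predictions.
    """
    if not result.predictions:
        raise ValueError("no transition predictions in this replay")
    onsets = {}
    for s in SIDES:
        times = ic_onset_times(dataset.labels, s)
        acts = dataset.labels[f"{s}_activity"].to_numpy()
        all_t = dataset.times
        steady = np.array(
            [WalkingActivity(int(acts[np.searchsorted(all_t, t)])).is_steady for t in times]
        )
        onsets[s] = times[steady]
    rows = []
    for s, p in result.predictions:
        later = onsets[s][onsets[s] > p.issued_at + 1e-9]
        if later.size == 0:
            continue
        real_hc = float(later[0])
        rows.append(
            {
                "side": s,
                "issued_at": p.issued_at,
                "event": int(p.event),
                "factor": p.factor,
                "mgct": p.mgct,
                "predicted_hc": p.predicted_hc,
                "real_hc": real_hc,
                "mpt_ms": (real_hc - p.issued_at) * 1000.0,
                "mtd_ms": (real_hc - p.predicted_hc) * 1000.0,
                "upcoming": int(p.upcoming),
                "is_upper_bound": p.is_upper_bound,
            }
        )
    return TimingReport(table=pd.DataFrame(rows))
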