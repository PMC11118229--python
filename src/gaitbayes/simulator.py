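"""Seeded synthetic generator of bilateral labeled gait streams.

The recognizer's original training/testing data (subject recordings) are not
distributable, so this module generates streams with the statistical
structure the recognizer assumes:

* per-limb gait cycles partitioned into the eight events by the standard
  phase proportions (:data:`gaitbayes.core.PHASE_BOUNDS`);
* a half-cycle bilateral offset — the left limb's phase is exactly the right
  limb's phase + 0.5 (mod 1), so the emitted (right, left) event pairs always
  lie inside the bilateral event-pair table, and the left limb's activity
  changes half a cycle after the right limb's, which keeps activity pairs
  inside the bilateral activity-pair table;
* the two ambulation protocols, each a fixed activity sequence
  (direction 1: LW→LC→CW→CL→LW→LC→CW→CL→LW; direction 2 with LCC/CCW/CCL),
  steady segments lasting a configurable number of cycles and every
  transition exactly one gait cycle;
* class-conditional Gaussian feature emissions.  Activity sets the mean of
  the yaw-rate channels with physical sign conventions (CW turns drive
  negative trunk yaw rate, CCW positive, LW near zero; transitions
  intermediate, loading trunk vs. thigh/shank channels differently so all
  seven activities are separable), and the gait event sets the means of the
  ipsilateral pitch-rate channels through a within-cycle profile.  The
  ``separation`` scale multiplies all class-mean magnitudes; ``noise_sd`` is
  the i.i.d. Gaussian noise added to every channel.

Cycle durations are drawn once per cycle: ``cycle_time`` times a Gaussian
factor with coefficient of variation ``cycle_cv`` (clipped to ±50%).  All
randomness flows from a single seeded generator, so streams are reproducible.
This generator makes no claim of biomechanical realism — no kinematic chain,
no sensor bias or drift; it provides separable, table-consistent streams for
testing the inference machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import WalkingActivity, event_at_phase
from .preprocess import CHANNELS, read_frames_csv, write_frames_csv

__all__ = [
    "EmissionModel",
    "ProtocolSpec",
    "GaitDataset",
    "generate_labels",
    "emit_features",
    "generate_dataset",
    "concat_datasets",
    "ic_onset_times",
]

LABEL_COLUMNS = (
    "time",
    "right_activity",
    "right_event",
    "right_phase",
    "right_cycle",
    "left_activity",
    "left_event",
    "left_phase",
    "left_cycle",
)

# Activity -> yaw-rate coefficient (units of `separation`).  Trunk and
# limb channels are loaded differently so that e.g. LC (trunk leads the turn)
# and CL (limbs trail out of the turn) remain separable.
_TRUNK_YAW = {1: 0.0, 2: -1.0, 3: 1.0, 4: -0.7, 5: 0.7, 6: -0.3, 7: 0.3}
_LIMB_YAW = {1: 0.0, 2: -1.0, 3: 1.0, 4: -0.3, 5: 0.3, 6: -0.7, 7: 0.7}

# Gait event -> pitch-rate coefficients for the ipsilateral thigh and shank.
# Thigh and shank pitch velocities are roughly sinusoidal over a cycle, so the
# (thigh, shank) mean trajectory is a circle traversed once per cycle, plus a
# sharp heel-strike bump around IC.  When per-sample phases are available the
# means follow the smooth trajectory (so filtered signals stay close to the
# class-conditional statistics the recognizer learns); a label stream without
# phases falls back to each event's center-of-window value.
_EVENT_CENTER = {1: 0.01, 2: 0.06, 3: 0.20, 4: 0.40, 5: 0.55, 6: 0.665, 7: 0.80, 8: 0.935}
_IC_BUMP_AMP = 3.0       # heel-strike transient amplitude (thigh +, shank -)
_IC_BUMP_WIDTH = 0.025   # bump SD, in cycle fraction
_IC_BUMP_CENTER = 0.985  # just before contact: after causal low-pass
                         # filtering the delayed peak falls inside IC


def _pitch_profile(phase: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(thigh, shank) pitch-rate coefficients at cycle fraction ``phase``."""
    phase = np.asarray(phase, dtype=float) % 1.0
    d = (phase - _IC_BUMP_CENTER + 0.5) % 1.0 - 0.5  # wrapped distance
    bump = _IC_BUMP_AMP * np.exp(-0.5 * (d / _IC_BUMP_WIDTH) ** 2)
    return np.cos(2 * np.pi * phase) + bump, np.sin(2 * np.pi * phase) - bump


_THIGH_PITCH = {
    e: float(_pitch_profile(np.array(c))[0]) for e, c in _EVENT_CENTER.items()
}
_SHANK_PITCH = {
    e: float(_pitch_profile(np.array(c))[1]) for e, c in _EVENT_CENTER.items()
}


@dataclass(frozen=True)
class EmissionModel:
    """Class-conditional Gaussian emissions for the twelve channels.

    ``separation`` (deg/s) scales every class-mean magnitude; ``noise_sd``
    (deg/s) is the common Gaussian noise standard deviation.  With
    ``noise_sd = 0`` features equal the class means exactly.
    """

    separation: float = 60.0
    noise_sd: float = 12.0

    def mean_matrix(self, labels: pd.DataFrame) -> np.ndarray:
        """(n, 12) matrix of per-sample channel means given the labels."""
        ra = labels["right_activity"].to_numpy()
        la = labels["left_activity"].to_numpy()
        re = labels["right_event"].to_numpy()
        le = labels["left_event"].to_numpy()
        sep = self.separation

        def lut(table, codes):
            arr = np.array([table[c] for c in sorted(table)])
            return arr[codes - 1]

        if "right_phase" in labels.columns:
            r_thigh, r_shank = _pitch_profile(labels["right_phase"].to_numpy())
            l_thigh, l_shank = _pitch_profile(labels["left_phase"].to_numpy())
        else:
            r_thigh, r_shank = lut(_THIGH_PITCH, re), lut(_SHANK_PITCH, re)
            l_thigh, l_shank = lut(_THIGH_PITCH, le), lut(_SHANK_PITCH, le)

        trunk = 0.5 * (lut(_TRUNK_YAW, ra) + lut(_TRUNK_YAW, la)) * sep
        means: Dict[str, np.ndarray] = {
            "pelvis_yaw": trunk,
            "chest_yaw": 0.9 * trunk,
            "pelvis_roll": 0.3 * trunk,
            "chest_pitch": 0.2 * np.abs(trunk),
            "right_thigh_yaw": lut(_LIMB_YAW, ra) * sep,
            "right_shank_yaw": 0.8 * lut(_LIMB_YAW, ra) * sep,
            "left_thigh_yaw": lut(_LIMB_YAW, la) * sep,
            "left_shank_yaw": 0.8 * lut(_LIMB_YAW, la) * sep,
            "right_thigh_pitch": r_thigh * sep,
            "right_shank_pitch": r_shank * sep,
            "left_thigh_pitch": l_thigh * sep,
            "left_shank_pitch": l_shank * sep,
        }
        return np.column_stack([means[c] for c in CHANNELS])


_DIRECTION_SEGMENTS = {
    1: [1, 4, 2, 6, 1, 4, 2, 6, 1],  # LW LC CW CL LW LC CW CL LW
    2: [1, 5, 3, 7, 1, 5, 3, 7, 1],  # LW LCC CCW CCL LW LCC CCW CCL LW
}


@dataclass(frozen=True)
class ProtocolSpec:
    """One ambulation-protocol trial.

    direction 1 walks LW→LC→CW→CL→… ; direction 2 uses the
    counterclockwise transitions.  Steady segments last
    ``cycles_per_steady`` gait cycles; transitions exactly one.
    """

    direction: int = 1
    cycles_per_steady: int = 3
    cycle_time: float = 1.1     # s, mean gait cycle duration
    cycle_cv: float = 0.05      # coefficient of variation of cycle duration
    fs: float = 100.0           # Hz
    seed: int = 0

    def __post_init__(self):
        if self.direction not in _DIRECTION_SEGMENTS:
            raise ValueError("direction must be 1 or 2")
        if self.cycles_per_steady < 1:
            raise ValueError("cycles_per_steady must be >= 1")

    def segment_sequence(self) -> List[WalkingActivity]:
        return [WalkingActivity(c) for c in _DIRECTION_SEGMENTS[self.direction]]

    def cycle_activities(self) -> List[WalkingActivity]:
        """Per-gait-cycle activity codes of the whole trial."""
        out: List[WalkingActivity] = []
        for a in self.segment_sequence():
            out.extend([a] * (1 if a.is_transition else self.cycles_per_steady))
        return out


def generate_labels(spec: ProtocolSpec, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Per-sample bilateral (activity, event) labels for one trial.

    Columns: time, then per side the activity code, event code, cycle phase
    in [0, 1) and cycle index (the left limb's first half-cycle has index -1).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    acts = np.array([int(a) for a in spec.cycle_activities()])
    ncy = len(acts)
    if spec.cycle_cv > 0:
        dur = spec.cycle_time * (1.0 + spec.cycle_cv * rng.standard_normal(ncy))
        dur = np.clip(dur, 0.5 * spec.cycle_time, 1.5 * spec.cycle_time)
    else:
        dur = np.full(ncy, spec.cycle_time)
    starts = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    total = starts[-1] + dur[-1]
    n = int(np.floor(total * spec.fs))
    t = np.arange(n) / spec.fs

    ridx = np.searchsorted(starts, t, side="right") - 1
    rphase = (t - starts[ridx]) / dur[ridx]
    rphase = np.clip(rphase, 0.0, np.nextafter(1.0, 0.0))
    ract = acts[ridx]
    revent = event_at_phase(rphase)

    # Left limb: exact half-cycle phase offset; its activity switches at the
    # middle of each right cycle (a left cycle spans mid-cycle to mid-cycle
    # and carries the activity of the right cycle it started in).
    lphase = (rphase + 0.5) % 1.0
    levent = event_at_phase(lphase)
    lidx = np.where(rphase >= 0.5, ridx, ridx - 1)
    lact = acts[np.clip(lidx, 0, None)]

    return pd.DataFrame(
        {
            "time": t,
            "right_activity": ract.astype(np.int64),
            "right_event": revent,
            "right_phase": rphase,
            "right_cycle": ridx.astype(np.int64),
            "left_activity": lact.astype(np.int64),
            "left_event": levent,
            "left_phase": lphase,
            "left_cycle": lidx.astype(np.int64),
        }
    )


def emit_features(
    labels: pd.DataFrame,
    emission: Optional[EmissionModel] = None,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw the 12-channel frame stream given per-sample labels."""
    if emission is None:
        emission = EmissionModel()
    if rng is None:
        rng = np.random.default_rng(seed)
    means = emission.mean_matrix(labels)
    if emission.noise_sd > 0:
        means = means + rng.normal(scale=emission.noise_sd, size=means.shape)
    frames = pd.DataFrame(means, columns=list(CHANNELS))
    frames.insert(0, "time", labels["time"].to_numpy())
    return frames


@dataclass
class GaitDataset:
    """A frame stream with parallel bilateral labels."""

    frames: pd.DataFrame
    labels: pd.DataFrame
    fs: float = 100.0

    def __post_init__(self):
        if len(self.frames) != len(self.labels):
            raise ValueError("frames and labels must have the same length")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.labels["time"].to_numpy()

    def label_codes(self, side: str) -> np.ndarray:
        """(n, 2) true (activity, event) codes for one limb."""
        return self.labels[[f"{side}_activity", f"{side}_event"]].to_numpy()

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_frames_csv(self.frames, directory / "frames.csv")
        self.labels.to_csv(directory / "labels.csv", index=False)

    @classmethod
    def read(cls, directory, fs: float = 100.0) -> "GaitDataset":
        directory = Path(directory)
        frames = read_frames_csv(directory / "frames.csv")
        labels = pd.read_csv(directory / "labels.csv")
        return cls(frames=frames, labels=labels, fs=fs)


def generate_dataset(
    spec: ProtocolSpec,
    emission: Optional[EmissionModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> GaitDataset:
    """Labels + emitted features for one trial, from a single seeded RNG."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    labels = generate_labels(spec, rng=rng)
    frames = emit_features(labels, emission=emission, rng=rng)
    return GaitDataset(frames=frames, labels=labels, fs=spec.fs)


def concat_datasets(datasets) -> GaitDataset:
    """Concatenate trials end to end, shifting time stamps to stay increasing."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    fs = datasets[0].fs
    frames, labels = [], []
    offset = 0.0
    for ds in datasets:
        f = ds.frames.copy()
        l = ds.labels.copy()
        f["time"] = f["time"] + offset
        l["time"] = l["time"] + offset
        offset = float(l["time"].iloc[-1]) + 1.0 / fs
        frames.append(f)
        labels.append(l)
    return GaitDataset(
        frames=pd.concat(frames, ignore_index=True),
        labels=pd.concat(labels, ignore_index=True),
        fs=fs,
    )


def ic_onset_times(labels: pd.DataFrame, side: str) -> np.ndarray:
    """True IC onset times of one limb (event enters code 1)."""
    ev = labels[f"{side}_event"].to_numpy()
    onset = np.flatnonzero((ev == 1) & (np.roll(ev, 1) != 1))
    if len(ev) > 0 and ev[0] == 1:
        onset = np.union1d(onset, [0])
    return labels["time"].to_numpy()[onset]
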