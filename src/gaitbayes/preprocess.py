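"""Low-pass filtering and per-limb feature assembly.

Raw input is a frame stream: one row per sample at the configured rate
(default 100 Hz), a ``time`` column in seconds and twelve angular-velocity
channels (deg/s) from IMUs on the pelvis, chest, thighs and shanks.  Human
walking content lies below 6 Hz, so every channel is passed through a causal
second-order Butterworth low-pass filter (6 Hz cutoff) before recognition.

Each limb's recognizer is unilateral: it consumes the trunk channels plus the
ipsilateral thigh/shank channels (eight features per limb by default; the
full 12-channel set is also supported via the ``channels`` argument).
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "CHANNELS",
    "RIGHT_FEATURES",
    "LEFT_FEATURES",
    "mirror_channel",
    "feature_channels",
    "lowpass",
    "lowpass_frames",
    "assemble_features",
    "read_frames_csv",
    "write_frames_csv",
]

#: The twelve angular-velocity channels, in canonical column order.  The
#: published feature list repeats "right shank pitch" where limb symmetry
#: (with "left thigh pitch") implies right thigh pitch; the corrected name is
#: used here.
CHANNELS: Tuple[str, ...] = (
    "pelvis_yaw",
    "chest_yaw",
    "left_thigh_yaw",
    "right_thigh_yaw",
    "pelvis_roll",
    "left_shank_yaw",
    "right_shank_yaw",
    "chest_pitch",
    "right_shank_pitch",
    "right_thigh_pitch",
    "left_shank_pitch",
    "left_thigh_pitch",
)

#: Default unilateral feature subset for the right-limb recognizer:
#: trunk channels + ipsilateral segment channels.
RIGHT_FEATURES: Tuple[str, ...] = (
    "pelvis_yaw",
    "chest_yaw",
    "pelvis_roll",
    "chest_pitch",
    "right_thigh_yaw",
    "right_shank_yaw",
    "right_shank_pitch",
    "right_thigh_pitch",
)


def mirror_channel(name: str) -> str:
    """Swap left<->right in a channel name; trunk channels map to themselves."""
    if name.startswith("left_"):
        return "right_" + name[len("left_"):]
    if name.startswith("right_"):
        return "left_" + name[len("right_"):]
    return name


LEFT_FEATURES: Tuple[str, ...] = tuple(mirror_channel(c) for c in RIGHT_FEATURES)


def feature_channels(side: str, channels: Optional[Sequence[str]] = None) -> Tuple[str, ...]:
    """Channel selection for one limb's recognizer."""
    if channels is not None:
        return tuple(channels)
    if side == "right":
        return RIGHT_FEATURES
    if side == "left":
        return LEFT_FEATURES
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def lowpass(series, fs: float, fc: float = 6.0, order: int = 2) -> np.ndarray:
    """Causal Butterworth low-pass filter of one uniformly sampled series.

    Unit DC gain; the filter state is initialized to the first sample (step
    initialization) so a constant input passes through unchanged, which
    suppresses the startup transient of an online filter.

    Parameters
    ----------
    series : array-like, shape (n,)
    fs : sampling rate, Hz
    fc : cutoff (-3 dB) frequency, Hz; must satisfy ``fc < fs / 2``
    order : filter order, >= 1
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite-valued")
    if order < 1:
        raise ValueError("order must be >= 1")
    if not 0 < fc < fs / 2:
        raise ValueError(f"cutoff fc={fc} must lie in (0, fs/2)={fs / 2}")
    b, a = signal.butter(order, fc, btype="low", fs=fs)
    if x.size == 0:
        return x.copy()
    zi = signal.lfilter_zi(b, a) * x[0]
    y, _ = signal.lfilter(b, a, x, zi=zi)
    return y


def lowpass_frames(
    frames: pd.DataFrame, fs: float = 100.0, fc: float = 6.0, order: int = 2
) -> pd.DataFrame:
    """Filter every non-time column of a frame stream, per channel."""
    out = frames.copy()
    for col in out.columns:
        if col == "time":
            continue
        out[col] = lowpass(out[col].to_numpy(), fs=fs, fc=fc, order=order)
    return out


def assemble_features(
    frames: pd.DataFrame,
    side: str,
    channels: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, List[str]]:
    """Extract one limb's feature matrix from a frame stream.

    Returns ``(X, names)`` with ``X`` of shape (n_samples, n_features) in the
    order given by :func:`feature_channels`.  Raises ``ValueError`` if a
    configured channel is missing from the input.
    """
    names = list(feature_channels(side, channels))
    missing = [c for c in names if c not in frames.columns]
    if missing:
        raise ValueError(f"missing channel(s) in input frames: {missing}")
    return frames[names].to_numpy(dtype=float), names


def read_frames_csv(path) -> pd.DataFrame:
    """Read a frame-stream CSV (header row, ``time`` first column)."""
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise ValueError("first CSV column must be 'time' (seconds)")
    return df


def write_frames_csv(frames: pd.DataFrame, path) -> None:
    cols = ["time"] + [c for c in frames.columns if c != "time"]
    frames[cols].to_csv(path, index=False)
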