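"""In-memory containers: continuous sessions, epoched trials, ground truth.

All times are seconds relative to the start of the recording; within a
trial, stimulus times are stored absolutely in the event table and the
S1 stimulus of each trial defines that trial's local t = 0. Epoch
windows are half-open ``[start, end)`` in samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .montage import Montage

#: six movement types, pooled pairwise into three movement classes
MOVEMENT_TYPES = [
    "elbow_flexion", "elbow_extension",
    "supination", "pronation",
    "hand_open", "hand_close",
]
CLASS_OF_MOVEMENT = {
    "elbow_flexion": "flexion/extension",
    "elbow_extension": "flexion/extension",
    "supination": "pronation/supination",
    "pronation": "pronation/supination",
    "hand_open": "hand open/close",
    "hand_close": "hand open/close",
}
MOVEMENT_CLASSES = ["flexion/extension", "pronation/supination", "hand open/close"]

EVENT_COLUMNS = ["trial", "block", "movement", "s1_time", "s2_time"]


def pool_classes(movements: pd.Series) -> pd.Series:
    """Map the six movement types onto the three pooled classes."""
    unknown = set(movements.unique()) - set(CLASS_OF_MOVEMENT)
    if unknown:
        raise ValueError(f"unknown movement types: {sorted(unknown)}")
    return movements.map(CLASS_OF_MOVEMENT)


@dataclass
class RawSession:
    """One continuous multichannel recording of one subject and condition."""

    subject: str
    condition: Literal["ME", "MI"]
    signal: np.ndarray  # (channels, samples) µV
    sample_rate: float
    montage: Montage
    events: pd.DataFrame  # EVENT_COLUMNS, one row per trial
    onsets: pd.DataFrame | None = None  # filled by onset detection

    def __post_init__(self) -> None:
        if self.condition not in ("ME", "MI"):
            raise ValueError(f"condition must be ME or MI, got {self.condition!r}")
        if self.signal.shape[0] != len(self.montage):
            raise ValueError("channel count does not match montage size")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        s1 = self.events["s1_time"].to_numpy()
        if len(s1) > 1 and not np.all(np.diff(s1) > 0):
            raise ValueError("events must be strictly increasing in time")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def n_trials(self) -> int:
        return len(self.events)


@dataclass
class EpochSet:
    """Trials × channels × samples, aligned to S1 or to movement onset.

    ``meta`` keeps one row per retained trial (movement, class, onset,
    original index, artifact flag); ``bad_channels`` marks per-trial
    rejected channels so averages can exclude them.
    """

    data: np.ndarray  # (trials, channels, samples) µV
    alignment: Literal["S1", "onset"]
    window: tuple[float, float]  # seconds relative to alignment
    sample_rate: float
    montage: Montage
    meta: pd.DataFrame
    bad_channels: np.ndarray = field(default=None)  # bool (trials, channels)

    def __post_init__(self) -> None:
        n_trials, n_ch, n_samp = self.data.shape
        expected = int(round((self.window[1] - self.window[0]) * self.sample_rate))
        if n_samp != expected:
            raise ValueError(f"window implies {expected} samples, data has {n_samp}")
        if len(self.meta) != n_trials:
            raise ValueError("metadata rows must match trial count")
        if n_ch != len(self.montage):
            raise ValueError("channel count does not match montage")
        if self.bad_channels is None:
            self.bad_channels = np.zeros((n_trials, n_ch), dtype=bool)
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) / self.sample_rate

    def select(self, idx: np.ndarray | list[int]) -> "EpochSet":
        """Subset trials (positional indices), preserving order of ``idx``."""
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            data=self.data[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            bad_channels=self.bad_channels[idx],
        )

    def class_indices(self, movement_class: str) -> np.ndarray:
        return np.flatnonzero((self.meta["movement_class"] == movement_class).to_numpy())


@dataclass
class GroundTruth:
    """Hidden generator parameters, kept for parameter-recovery oracles."""

    subject: str
    condition: str
    mrcp_amp: dict[str, float]  # class -> true peak amplitude µV (negative)
    erd_depth: dict[str, dict[str, float]]  # band -> class -> depth in [0, 1)
    onset_times: pd.DataFrame  # trial, movement, onset_time (s, absolute)
    blink_topography: np.ndarray  # weights over all channels
    mu_topography: np.ndarray
    beta_topography: np.ndarray
    subject_factor: float = 1.0
    blink_times: np.ndarray | None = None
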