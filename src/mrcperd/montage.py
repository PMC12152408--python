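"""Electrode montages for the 5/10 extended sensorimotor layout.

Positions come from MNE's built-in 10-05 template head; only the label
set and 2-D scalp projection are kept here so downstream code never
depends on MNE objects.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np

# 61-channel sensorimotor-dense EEG layout (5/10 naming).
EEG61 = [
    "Fp1", "Fp2",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FFC5h", "FFC3h", "FFC1h", "FFC2h", "FFC4h", "FFC6h",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "FCC5h", "FCC3h", "FCC1h", "FCC2h", "FCC4h", "FCC6h",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CCP5h", "CCP3h", "CCP1h", "CCP2h", "CCP4h", "CCP6h",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "CPP5h", "CPP3h", "CPP1h", "CPP2h", "CPP4h", "CPP6h",
    "P3", "P1", "Pz", "P2", "P4",
]

# Reduced 16-channel layout for desk-scale runs; keeps the vertex, the
# frontal row (blink topography checks) and every ROI channel.
EEG16 = [
    "Fp1", "Fp2", "Fz", "Cz", "C3", "C1", "C4",
    "CCP3h", "CCP1h", "CP3", "CP1",
    "CPP3h", "CPP1h", "P3", "P1", "Pz",
]

EOG_LABELS = ["EOG1", "EOG2", "EOG3"]
ACCEL_LABEL = "ACCEL1"

# Channel sets over which ERD is summarised, one per rhythm.
MU_ROI = ["CCP3h", "CP1", "CP3", "CPP3h", "P3", "P1"]
BETA_ROI = ["C3", "C1", "CCP3h", "CCP1h", "CP3", "CP1", "CPP3h", "CPP1h"]

MRCP_CHANNEL = "Cz"


@functools.lru_cache(maxsize=1)
def _template_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        try:
            mont = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # pragma: no cover - renamed template
            mont = mne.channels.make_standard_montage("colin27_1005")
    return {k: np.asarray(v) for k, v in mont.get_positions()["ch_pos"].items()}


def scalp_xy(labels: list[str]) -> np.ndarray:
    """2-D (x: left→right, y: posterior→anterior) positions in metres."""
    pos = _template_positions()
    return np.array([pos[lb][:2] for lb in labels], dtype=float)


@dataclass(frozen=True)
class Montage:
    """Channel names, kinds and flattened scalp positions of a recording.

    ``kinds`` uses ``EEG``/``EOG``/``ACCEL``; non-EEG channels get NaN
    positions.
    """

    names: tuple[str, ...]
    kinds: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n, 2), NaN for non-EEG

    def __post_init__(self) -> None:
        if len(self.names) != len(self.kinds) or len(self.names) != len(self.positions):
            raise ValueError("montage fields must have equal length")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def eeg_idx(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == "EEG"], dtype=int)

    @property
    def eog_idx(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == "EOG"], dtype=int)

    @property
    def accel_idx(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == "ACCEL"], dtype=int)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def eeg_names(self) -> list[str]:
        return [self.names[i] for i in self.eeg_idx]


def infer_kind(label: str) -> str:
    u = label.upper()
    if u.startswith("EOG"):
        return "EOG"
    if u.startswith("ACCEL") or u.startswith("ACC"):
        return "ACCEL"
    return "EEG"


def build_montage(eeg_labels: list[str], n_eog: int = 3, accel: bool = True) -> Montage:
    names = list(eeg_labels) + EOG_LABELS[:n_eog] + ([ACCEL_LABEL] if accel else [])
    kinds = ["EEG"] * len(eeg_labels) + ["EOG"] * n_eog + (["ACCEL"] if accel else [])
    pos = np.full((len(names), 2), np.nan)
    pos[: len(eeg_labels)] = scalp_xy(eeg_labels)
    return Montage(tuple(names), tuple(kinds), pos)


def default_eeg_labels(n_channels: int) -> list[str]:
    """Return the canonical label list for a supported channel count."""
    if n_channels == len(EEG61):
        return list(EEG61)
    if n_channels == len(EEG16):
        return list(EEG16)
    if n_channels <= len(EEG61):
        # Deterministic subset that always keeps vertex + ROI channels first.
        priority = [MRCP_CHANNEL] + MU_ROI + [c for c in BETA_ROI if c not in MU_ROI]
        rest = [c for c in EEG61 if c not in priority]
        return (priority + rest)[:n_channels]
    raise ValueError(f"no default layout with {n_channels} EEG channels")
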