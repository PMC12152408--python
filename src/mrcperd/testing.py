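"""Validation utilities: fixture builders and independent oracles.

These support the test suite and the acceptance script. The brute-force
ANOVA here is deliberately written from textbook marginal-mean sums of
squares, independent of :mod:`mrcperd.stats`, so the two can be checked
against each other.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import EpochSet, pool_classes
from .montage import build_montage, default_eeg_labels


def make_epochs(
    data: np.ndarray,
    movements: list[str] | None = None,
    alignment: str = "onset",
    window: tuple[float, float] | None = None,
    sample_rate: float = 256.0,
    n_eeg: int = 16,
) -> EpochSet:
    """Wrap a raw (trials, channels, samples) array into an EpochSet."""
    n_trials, n_ch, n_samp = data.shape
    eeg_labels = default_eeg_labels(n_eeg)
    mont = build_montage(eeg_labels, n_eog=max(n_ch - n_eeg - 1, 0), accel=n_ch > n_eeg)
    if len(mont) != n_ch:
        raise ValueError("channel count inconsistent with n_eeg")
    if window is None:
        window = (-n_samp / (2 * sample_rate), n_samp / (2 * sample_rate))
    if movements is None:
        movements = ["elbow_flexion"] * n_trials
    meta = pd.DataFrame({
        "orig_index": np.arange(n_trials),
        "trial": np.arange(n_trials),
        "block": np.zeros(n_trials, dtype=int),
        "movement": movements,
        "s1_time": np.zeros(n_trials),
        "align_time": np.zeros(n_trials),
        "artifact": False,
    })
    meta["movement_class"] = pool_classes(meta["movement"])
    return EpochSet(
        data=data, alignment=alignment, window=window, sample_rate=sample_rate,
        montage=mont, meta=meta,
    )


def brute_force_rm_anova(y: np.ndarray) -> dict:
    """Textbook cell-means fully-within-subjects 3-factor ANOVA.

    ``y``: (subjects, a, b, c). Returns {effect name: (ss_effect,
    ss_error, df_effect, df_error, F)}; effect names use "A", "B", "C"
    joined with " x ". Effects are inclusion–exclusion sums of marginal
    means; each error term is the subject-by-effect interaction.
    """
    n, A, B, C = y.shape
    axes = {"A": 1, "B": 2, "C": 3}
    levels = {1: A, 2: B, 3: C}

    def marg(keep):
        drop = tuple(i for i in range(4) if i not in keep)
        return y.mean(axis=drop, keepdims=True)

    def effect_ss(keep):
        total = np.zeros((1, A if 1 in keep else 1, B if 2 in keep else 1,
                          C if 3 in keep else 1))
        for r in range(len(keep) + 1):
            for sub in itertools.combinations(keep, r):
                total = total + (-1) ** (len(keep) - len(sub)) * marg(sub)
        others = int(np.prod([levels[ax] for ax in axes.values() if ax not in keep]))
        return float((n * others * total**2).sum())

    def subject_effect_ss(keep):
        keep_s = (0,) + keep
        total = np.zeros((n, A if 1 in keep else 1, B if 2 in keep else 1,
                          C if 3 in keep else 1))
        for r in range(len(keep_s) + 1):
            for sub in itertools.combinations(keep_s, r):
                total = total + (-1) ** (len(keep_s) - len(sub)) * marg(sub)
        others = int(np.prod([levels[ax] for ax in axes.values() if ax not in keep]))
        return float((others * total**2).sum())

    out = {}
    for r in range(1, 4):
        for keep in itertools.combinations((1, 2, 3), r):
            name = " x ".join(k for k, ax in axes.items() if ax in keep)
            df_e = int(np.prod([levels[ax] - 1 for ax in keep]))
            ss_e = effect_ss(keep)
            ss_err = subject_effect_ss(keep)
            df_err = df_e * (n - 1)
            f = (ss_e / df_e) / (ss_err / df_err)
            out[name] = (ss_e, ss_err, df_e, df_err, f)
    return out
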