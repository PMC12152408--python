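"""Movement-onset detection from accelerometer/glove traces.

ME onsets come from a derivative-threshold detector with local-extremum
refinement; MI trials have no overt movement, so their onsets are
imputed as the subject- and class-wise mean of the detected ME
latencies and applied identically to every MI trial of that cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import OnsetParams
from .containers import RawSession, pool_classes

log = logging.getLogger(__name__)


class NoOnsetError(RuntimeError):
    """The trace shows no supra-threshold step in the search window."""


@dataclass
class OnsetEstimate:
    trial: int
    onset_time: float  # s, same clock as the trace's time axis
    method: str  # "detected" | "imputed"
    derivative_peak: float = np.nan
    refinement_offset: float = 0.0  # s moved back from the landmark


def detect_onset(
    trace: np.ndarray,
    sample_rate: float,
    s2_time: float,
    baseline: tuple[float, float] | None = None,
    params: OnsetParams | None = None,
    trial: int = -1,
) -> OnsetEstimate:
    """Detect the movement onset in one accelerometer trace.

    ``trace`` is a 1-D signal whose time axis starts at t = 0; the
    movement step is searched in ``[s2_time, s2_time + search_window]``.
    The trace is smoothed (moving average), differentiated, and the
    first sample whose |derivative| exceeds ``threshold_k`` × the SD of
    the pre-S2 baseline derivative is the preliminary landmark; the
    onset is then refined backward to the first local extremum of the
    smoothed trace (a minimum before an upward step, a maximum before a
    downward one). Invariant under offset, positive scaling and sign
    flip of the trace.
    """
    params = params or OnsetParams()
    fs = sample_rate
    n = len(trace)
    if baseline is None:
        baseline = (0.0, s2_time)

    # causal (trailing) moving average so the smoothed step cannot start
    # rising before the physical one
    width = max(int(round(params.smooth_width * fs)), 1)
    x = np.asarray(trace, dtype=float)
    c = np.cumsum(np.concatenate([[0.0], x]))
    smooth = np.empty_like(x)
    smooth[width - 1:] = (c[width:] - c[:-width]) / width
    smooth[: width - 1] = c[1:width] / np.arange(1, width)
    deriv = np.diff(smooth, prepend=smooth[0])

    b0, b1 = (int(round(b * fs)) for b in baseline)
    b0, b1 = max(b0, 0), min(b1, n)
    if b1 - b0 < 2:
        raise ValueError("baseline window too short")
    sd = float(deriv[b0:b1].std())

    s2 = int(round(s2_time * fs))
    end = min(int(round((s2_time + params.search_window) * fs)), n)
    seg = np.abs(deriv[s2:end])
    thr = params.threshold_k * sd
    above = np.flatnonzero(seg > thr) if sd > 0 else np.flatnonzero(seg > 0)
    if len(above) == 0:
        raise NoOnsetError(f"trial {trial}: no derivative threshold crossing after S2")
    landmark = s2 + int(above[0])
    upward = deriv[landmark] > 0

    # refine: first local extremum of the smoothed trace just before the step
    lo = max(landmark - int(round(params.refine_window * fs)), 0)
    onset_idx = landmark
    for i in range(landmark - 1, lo, -1):
        if upward:
            if smooth[i] <= smooth[i - 1] and smooth[i] <= smooth[i + 1]:
                onset_idx = i
                break
        else:
            if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]:
                onset_idx = i
                break
    return OnsetEstimate(
        trial=trial,
        onset_time=onset_idx / fs,
        method="detected",
        derivative_peak=float(deriv[landmark]),
        refinement_offset=(landmark - onset_idx) / fs,
    )


def detect_session_onsets(
    session: RawSession, params: OnsetParams | None = None
) -> tuple[pd.DataFrame, int]:
    """Detect onsets for every ME trial of a session.

    Returns a table (trial, onset_time, method, latency) and the count
    of trials where detection failed (those are excluded from
    onset-aligned epoching downstream).
    """
    params = params or OnsetParams()
    accel = session.montage.accel_idx
    if len(accel) == 0:
        raise ValueError("session has no accelerometer channel")
    trace = session.signal[accel[0]]
    fs = session.sample_rate
    rows, failed = [], 0
    for _, ev in session.events.iterrows():
        s1, s2 = float(ev["s1_time"]), float(ev["s2_time"])
        lo = int(round(s1 * fs))
        hi = min(int(round((s2 + params.search_window + 0.1) * fs)), session.n_samples)
        try:
            est = detect_onset(
                trace[lo:hi], fs, s2 - s1, baseline=(0.0, s2 - s1),
                params=params, trial=int(ev["trial"]),
            )
        except NoOnsetError:
            failed += 1
            continue
        onset_abs = s1 + est.onset_time
        rows.append({
            "trial": int(ev["trial"]), "movement": ev["movement"],
            "onset_time": onset_abs, "latency": onset_abs - s2, "method": "detected",
        })
    if failed:
        log.info("onset detection failed on %d/%d trials", failed, len(session.events))
    if not rows:
        raise NoOnsetError("no onset detected in the whole session")
    table = pd.DataFrame(rows)
    table["movement_class"] = pool_classes(table["movement"])
    return table, failed


def impute_mi_onsets(me_onsets: pd.DataFrame, mi_session: RawSession) -> pd.DataFrame:
    """Impute MI onsets from the subject's detected ME latencies.

    The MI onset latency (relative to S2) of each movement class is the
    arithmetic mean of that class's detected ME latencies; it is applied
    identically to every MI trial of the class.
    """
    if len(me_onsets) == 0:
        raise ValueError("empty ME onset table")
    lat = me_onsets.groupby("movement_class")["latency"].mean()
    ev = mi_session.events.copy()
    ev["movement_class"] = pool_classes(ev["movement"])
    missing = set(ev["movement_class"].unique()) - set(lat.index)
    if missing:
        raise ValueError(f"no detected ME onsets for classes {sorted(missing)}")
    rows = [{
        "trial": int(r["trial"]), "movement": r["movement"],
        "movement_class": r["movement_class"],
        "onset_time": float(r["s2_time"]) + float(lat[r["movement_class"]]),
        "latency": float(lat[r["movement_class"]]), "method": "imputed",
    } for _, r in ev.iterrows()]
    return pd.DataFrame(rows)
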