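"""Motor features: MRCP waveform/peak and ERD waveform/minimum.

MRCP: the trial-averaged 0.3–3 Hz waveform in a −2.5..2.5 s window
around movement onset; the peak feature is the mean amplitude in a
200 ms window centred at the most negative deflection found at Cz
within the half second before onset.

ERD: per channel, band power is the squared band-filtered signal
averaged over trials; the ERD waveform is its percent change relative
to the mean power in a fixed pre-movement reference window (−1.5..−1 s),
so −50% means the band power halved. The ERD-min feature averages the
ERD waveform over the band's ROI channels and a 200 ms window centred
at onset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ERDParams, MRCPParams
from .containers import MOVEMENT_CLASSES, EpochSet
from .montage import Montage
from .preprocess import moving_average

FEATURES = ["mrcp_peak", "erd_mu_min", "erd_beta_min"]


def _masked_trial_mean(
    data: np.ndarray, bad: np.ndarray, subset: np.ndarray | None
) -> np.ndarray:
    """Mean over trials per channel, excluding per-trial bad channels."""
    if subset is not None:
        subset = np.asarray(subset, dtype=int)
        if subset.size == 0:
            raise ValueError("empty trial subset")
        data = data[subset]
        bad = bad[subset]
    w = (~bad).astype(float)[:, :, None]  # (trials, channels, 1)
    num = np.einsum("tcs,tcs->cs", data, np.broadcast_to(w, data.shape))
    den = w.sum(axis=0)  # (channels, 1)
    with np.errstate(invalid="ignore"):
        out = num / den
    return out


def compute_mrcp(
    epochs: EpochSet, params: MRCPParams, trial_subset: np.ndarray | None = None
) -> np.ndarray:
    """Trial-averaged MRCP waveform, channels × samples (µV).

    Channels flagged artifactual in a trial do not contribute to that
    trial's average. ``epochs`` must already be onset-aligned and
    band-filtered to ``params.band``.
    """
    if epochs.alignment != "onset":
        raise ValueError("MRCP epochs must be aligned to movement onset")
    return _masked_trial_mean(epochs.data, epochs.bad_channels, trial_subset)


def mrcp_peak(
    waveform: np.ndarray,
    times: np.ndarray,
    montage: Montage,
    params: MRCPParams,
) -> float:
    """MRCP peak feature (µV) from an averaged waveform.

    The extremum is the most negative sample (or largest |amplitude|
    with ``polarity='absolute'``) at the configured channel inside the
    search window; the returned value is the mean over a
    ``peak_avg_width`` window centred there. The search is clipped so
    the averaging window always fits inside the epoch.
    """
    if params.channel not in montage.names:
        raise ValueError(f"channel {params.channel!r} missing from montage")
    trace = np.asarray(waveform)[montage.index(params.channel)]
    hw = params.peak_avg_width / 2.0
    lo, hi = params.peak_search
    searchable = (times >= max(lo, times[0] + hw)) & (times <= min(hi, times[-1] - hw))
    idx = np.flatnonzero(searchable)
    if idx.size == 0:
        raise ValueError("peak search window does not fit inside the epoch")
    seg = trace[idx]
    if params.polarity == "absolute":
        k = idx[int(np.argmax(np.abs(seg)))]
    else:
        k = idx[int(np.argmin(seg))]
    dt = times[1] - times[0]
    half = int(round(hw / dt))
    return float(trace[k - half : k + half + 1].mean())


def compute_erd(
    epochs: EpochSet, params: ERDParams, trial_subset: np.ndarray | None = None
) -> np.ndarray:
    """ERD% waveform, channels × samples.

    ``epochs`` carry the band-filtered signal; power is its square,
    averaged over the trial subset per channel, optionally smoothed
    (``power_smooth`` seconds of moving average) before normalisation
    to the reference-window mean.
    """
    if epochs.alignment != "onset":
        raise ValueError("ERD epochs must be aligned to movement onset")
    power = _masked_trial_mean(epochs.data**2, epochs.bad_channels, trial_subset)
    return erd_from_power(power, epochs.times, epochs.sample_rate, params)


def erd_from_power(
    power: np.ndarray, times: np.ndarray, sample_rate: float, params: ERDParams
) -> np.ndarray:
    """Percent-change normalisation of a trial-averaged power trace."""
    if params.power_smooth > 0:
        power = moving_average(power, int(round(params.power_smooth * sample_rate)))
    r0, r1 = params.reference_window
    ref_mask = (times >= r0) & (times < r1)
    if not ref_mask.any():
        raise ValueError("reference window outside the epoch")
    rw = power[:, ref_mask].mean(axis=1, keepdims=True)
    if np.any(rw <= 0):
        raise ValueError("reference-window power is not positive; cannot normalise")
    return 100.0 * (power - rw) / rw


def erd_min(
    erd_waveform: np.ndarray,
    times: np.ndarray,
    montage: Montage,
    params: ERDParams,
) -> float:
    """ERD-min feature (%): ROI-averaged ERD over ±100 ms around onset."""
    rows = [montage.index(c) for c in params.roi if c in montage.names]
    if not rows:
        raise ValueError("no ROI channel present in the montage")
    roi = np.asarray(erd_waveform)[rows]
    roi = roi[~np.isnan(roi).all(axis=1)]
    if roi.size == 0:
        raise ValueError("all ROI channels missing/NaN")
    hw = params.min_avg_width / 2.0
    mask = (times >= -hw) & (times <= hw)
    return float(np.nanmean(roi.mean(axis=0)[mask]))


def extract_features(
    epochs_by_cell: dict[tuple[str, str], dict[str, EpochSet]],
    mrcp_params: MRCPParams,
    erd_mu: ERDParams,
    erd_beta: ERDParams,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """One feature row per subject × condition × class × feature.

    ``epochs_by_cell`` maps (subject, condition) to the three aligned
    epoch sets ``{"mrcp": ..., "mu": ..., "beta": ...}`` covering all
    classes; class subsetting happens here. Deterministic given inputs.
    """
    classes = classes or MOVEMENT_CLASSES
    rows = []
    for (subject, condition), sets in sorted(epochs_by_cell.items()):
        for cls in classes:
            for feat, key, prm in (
                ("mrcp_peak", "mrcp", mrcp_params),
                ("erd_mu_min", "mu", erd_mu),
                ("erd_beta_min", "beta", erd_beta),
            ):
                ep = sets[key]
                idx = ep.class_indices(cls)
                if idx.size == 0:
                    raise ValueError(
                        f"{subject}/{condition}/{cls}: no trials for {feat}"
                    )
                try:
                    if feat == "mrcp_peak":
                        wf = compute_mrcp(ep, prm, idx)
                        value = mrcp_peak(wf, ep.times, ep.montage, prm)
                    else:
                        wf = compute_erd(ep, prm, idx)
                        value = erd_min(wf, ep.times, ep.montage, prm)
                except ValueError as err:
                    raise ValueError(f"{subject}/{condition}/{cls}/{feat}: {err}") from err
                rows.append({
                    "subject": subject, "condition": condition, "movement_class": cls,
                    "feature": feat, "n_trials": int(idx.size), "value": value,
                })
    return pd.DataFrame(rows)
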