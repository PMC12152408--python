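"""Preprocessing: filtering, SOBI ocular cleaning, trial rejection, CAR.

The cleaning chain runs on continuous data in the recorded order:
broadband 0.3–100 Hz band-pass, second-order blind identification
(SOBI) of EEG+EOG into source components, automatic flagging of ocular
components by spectral and topographic features, reconstruction without
them, then (after epoching) amplitude/kurtosis trial rejection and
common average re-referencing that excludes the per-trial bad channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .config import PreprocParams
from .containers import EpochSet, RawSession
from .montage import Montage

log = logging.getLogger(__name__)


# --------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------

def bandpass(
    signal: np.ndarray,
    low: float,
    high: float,
    sample_rate: float,
    order: int = 4,
    zero_phase: bool = True,
) -> np.ndarray:
    """Butterworth band-pass along the last axis.

    ``zero_phase`` applies the filter forward and backward (no group
    delay, doubled effective order) — the default everywhere offline so
    peak latencies are not shifted.
    """
    nyq = sample_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={nyq:g})")
    sos = sps.butter(order, (low, high), btype="bandpass", fs=sample_rate, output="sos")
    if zero_phase:
        return sps.sosfiltfilt(sos, signal, axis=-1)
    return sps.sosfilt(sos, signal, axis=-1)


def moving_average(x: np.ndarray, width_samples: int) -> np.ndarray:
    """Centred moving average along the last axis (edges replicated)."""
    if width_samples <= 1:
        return x
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(x, size=width_samples, axis=-1, mode="nearest")


# --------------------------------------------------------------------
# SOBI
# --------------------------------------------------------------------

@dataclass
class UnmixingModel:
    """SOBI decomposition of a multichannel recording."""

    mixing: np.ndarray  # (channels, components)
    unmixing: np.ndarray  # (components, channels)
    lags: np.ndarray
    whitener: np.ndarray = field(repr=False, default=None)
    off_criterion: np.ndarray = None  # per-sweep joint-diagonality criterion
    ocular: np.ndarray = None  # bool flags per component
    features: pd.DataFrame | None = None
    converged: bool = True

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def sources(self, signal: np.ndarray) -> np.ndarray:
        return self.unmixing @ (signal - signal.mean(axis=1, keepdims=True))


def _joint_diagonalize(
    mats: np.ndarray, max_sweeps: int = 100, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Jacobi-style joint diagonalization of symmetric matrices.

    Iterative Givens rotations minimising the summed squared
    off-diagonal criterion (Cardoso & Souloumiac). Returns the
    orthogonal matrix ``Q`` (so ``Q.T @ M @ Q`` is ~diagonal for every
    ``M``), the per-sweep criterion trace, and a convergence flag.
    """
    m, k, _ = mats.shape
    C = mats.copy()
    Q = np.eye(k)

    def off(c):
        return float(sum(np.sum(ci**2) - np.sum(np.diag(ci) ** 2) for ci in c))

    crit = [off(C)]
    converged = False
    for _ in range(max_sweeps):
        rotated = False
        for p in range(k - 1):
            for q in range(p + 1, k):
                ton = C[:, p, p] - C[:, q, q]
                toff = C[:, p, q] + C[:, q, p]
                g11 = ton @ ton
                g12 = ton @ toff
                g22 = toff @ toff
                theta = 0.5 * np.arctan2(2 * g12, g11 - g22 + np.hypot(g11 - g22, 2 * g12))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) < tol:
                    continue
                rotated = True
                rot_p = c * C[:, :, p] + s * C[:, :, q]
                rot_q = -s * C[:, :, p] + c * C[:, :, q]
                C[:, :, p], C[:, :, q] = rot_p, rot_q
                rot_p = c * C[:, p, :] + s * C[:, q, :]
                rot_q = -s * C[:, p, :] + c * C[:, q, :]
                C[:, p, :], C[:, q, :] = rot_p, rot_q
                qp = c * Q[:, p] + s * Q[:, q]
                qq = -s * Q[:, p] + c * Q[:, q]
                Q[:, p], Q[:, q] = qp, qq
        crit.append(off(C))
        if not rotated:
            converged = True
            break
    return Q, np.asarray(crit), converged


def sobi_decompose(
    signal: np.ndarray,
    sample_rate: float | None = None,
    lags: np.ndarray | None = None,
    max_sweeps: int = 100,
) -> UnmixingModel:
    """Second-order blind identification of ``signal`` (channels × samples).

    Whitens via the zero-lag covariance eigendecomposition (reduced to
    the effective rank when the covariance is singular), then jointly
    diagonalizes the symmetrized time-lagged covariances at ``lags``
    (default 1..0.2·fs samples, ≈0–200 ms).
    """
    n_ch, n_samp = signal.shape
    if n_samp < 10 * n_ch:
        raise ValueError("SOBI needs samples >> channels")
    if lags is None:
        if sample_rate is None:
            raise ValueError("either lags or sample_rate must be given")
        lags = np.arange(1, max(int(round(0.2 * sample_rate)), 2))
    lags = np.asarray(lags, dtype=int)

    x = signal - signal.mean(axis=1, keepdims=True)
    c0 = (x @ x.T) / n_samp
    evals, evecs = np.linalg.eigh(c0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int(np.sum(evals > max(evals.max(), 1e-30) * 1e-10))
    if rank < n_ch:
        log.warning("rank-deficient covariance: reducing %d channels to rank %d", n_ch, rank)
    evals, evecs = evals[:rank], evecs[:, :rank]
    whitener = (evecs / np.sqrt(evals)).T  # (rank, channels)
    z = whitener @ x

    mats = np.empty((len(lags), rank, rank))
    for i, lag in enumerate(lags):
        r = (z[:, :-lag] @ z[:, lag:].T) / (n_samp - lag)
        mats[i] = 0.5 * (r + r.T)

    q, crit, converged = _joint_diagonalize(mats, max_sweeps=max_sweeps)
    if not converged:
        warnings.warn("SOBI joint diagonalization did not fully converge; "
                      "returning the best iterate", RuntimeWarning, stacklevel=2)
    unmixing = q.T @ whitener
    mixing = np.linalg.pinv(unmixing)
    return UnmixingModel(
        mixing=mixing, unmixing=unmixing, lags=lags, whitener=whitener,
        off_criterion=crit, converged=converged,
    )


def flag_ocular_components(
    model: UnmixingModel,
    signal: np.ndarray,
    eog_signals: np.ndarray | None,
    montage: Montage,
    sample_rate: float,
    params: PreprocParams | None = None,
) -> np.ndarray:
    """Flag components that look ocular.

    A component is ocular iff its relative spectral power below
    ``ocular_low_freq`` exceeds ``ocular_p_low`` AND (its max |corr|
    with an EOG channel exceeds ``ocular_r_eog`` OR the frontal
    concentration of its mixing column exceeds ``ocular_f_front``).
    Without EOG channels only the frequency + topography pair is used.
    """
    params = params or PreprocParams()
    sources = model.sources(signal)
    n_comp = sources.shape[0]
    if n_comp == 0:
        model.ocular = np.zeros(0, dtype=bool)
        return model.ocular

    nper = min(int(4 * sample_rate), sources.shape[1])
    freqs, psd = sps.welch(sources, fs=sample_rate, nperseg=nper, axis=-1)
    low = freqs <= params.ocular_low_freq
    p_low = psd[:, low].sum(axis=1) / np.maximum(psd.sum(axis=1), 1e-30)

    if eog_signals is not None and len(eog_signals):
        r = np.corrcoef(np.vstack([sources, eog_signals]))
        r_eog = np.abs(r[:n_comp, n_comp:]).max(axis=1)
    else:
        log.info("no EOG channels; ocular flagging uses frequency+topography only")
        r_eog = np.zeros(n_comp)

    eeg = montage.eeg_idx
    y = montage.positions[eeg, 1]
    # anterior rows (Fp/AF/F, y >= ~0.045 m on the template head); an
    # absolute cut, not a percentile, so posterior-heavy layouts do not
    # mislabel central channels as frontal
    frontal = y >= 0.045
    if not frontal.any():
        frontal = y > np.nanmedian(y)
    colw = np.abs(model.mixing[eeg, :])
    f_front = colw[frontal].sum(axis=0) / np.maximum(colw.sum(axis=0), 1e-30)

    if eog_signals is not None and len(eog_signals):
        flags = (p_low > params.ocular_p_low) & (
            (r_eog > params.ocular_r_eog) | (f_front > params.ocular_f_front)
        )
    else:
        flags = (p_low > params.ocular_p_low) & (f_front > params.ocular_f_front)

    model.ocular = flags
    model.features = pd.DataFrame(
        {"low_freq_fraction": p_low, "max_eog_corr": r_eog, "frontal_concentration": f_front,
         "ocular": flags}
    )
    return flags


def remove_components(
    signal: np.ndarray, model: UnmixingModel, flags: np.ndarray | None = None
) -> np.ndarray:
    """Reconstruct the recording with the flagged source rows zeroed."""
    flags = model.ocular if flags is None else np.asarray(flags, dtype=bool)
    if flags is None:
        raise ValueError("no flags given and model has none")
    if flags.shape[0] != model.n_components:
        raise ValueError("flags length must equal component count")
    if flags.all() and flags.size:
        raise ValueError("refusing to remove all components (zero signal)")
    mean = signal.mean(axis=1, keepdims=True)
    sources = model.unmixing @ (signal - mean)
    sources[flags] = 0.0
    return model.mixing @ sources + mean


def clean_session(session: RawSession, params: PreprocParams) -> tuple[RawSession, UnmixingModel]:
    """Filter + SOBI-clean the EEG/EOG channels of a session, in place order."""
    mont = session.montage
    phys = np.concatenate([mont.eeg_idx, mont.eog_idx])
    low, high = params.filter_band(session.sample_rate)
    sig = session.signal.copy()
    sig[phys] = bandpass(sig[phys], low, high, session.sample_rate,
                         order=params.filter_order, zero_phase=params.zero_phase)
    lags = np.arange(1, max(int(round(params.sobi_max_lag_s * session.sample_rate)), 2))
    model = sobi_decompose(sig[phys], session.sample_rate, lags=lags,
                           max_sweeps=params.sobi_max_sweeps)
    sub_mont = Montage(
        tuple(mont.names[i] for i in phys), tuple(mont.kinds[i] for i in phys),
        mont.positions[phys],
    )
    flag_ocular_components(model, sig[phys], sig[mont.eog_idx], sub_mont,
                           session.sample_rate, params)
    if model.ocular.any():
        sig[phys] = remove_components(sig[phys], model)
    cleaned = RawSession(
        subject=session.subject, condition=session.condition, signal=sig,
        sample_rate=session.sample_rate, montage=mont, events=session.events,
        onsets=session.onsets,
    )
    return cleaned, model


# --------------------------------------------------------------------
# trial rejection
# --------------------------------------------------------------------

@dataclass
class RejectionReport:
    """Per trial × channel artifact metrics and the resulting decisions."""

    amplitude: np.ndarray  # (trials, eeg_channels) peak-to-peak µV
    kurtosis: np.ndarray  # excess kurtosis
    flagged: np.ndarray  # bool (trials, eeg_channels)
    rejected_trials: np.ndarray  # positional indices into the input EpochSet
    amp_threshold: float
    kurt_threshold: float
    k_sd: float
    channel_fraction_limit: float

    def to_frame(self, channel_names: list[str]) -> pd.DataFrame:
        n_t, n_c = self.amplitude.shape
        return pd.DataFrame({
            "trial": np.repeat(np.arange(n_t), n_c),
            "channel": np.tile(channel_names, n_t),
            "amplitude": self.amplitude.ravel(),
            "kurtosis": self.kurtosis.ravel(),
            "flagged": self.flagged.ravel(),
        })


def reject_artifacts(
    epochs: EpochSet,
    k_sd: float = 5.0,
    channel_fraction_limit: float = 0.25,
) -> tuple[EpochSet, RejectionReport]:
    """Drop artifactual trials, mark artifactual channels.

    Per trial × EEG channel, peak-to-peak amplitude and excess kurtosis
    are computed; each metric's outlier threshold is the *median* of the
    pooled trial×channel values plus ``k_sd`` times their SD (the robust
    centre keeps the threshold itself unpolluted by the outliers being
    hunted). A channel in a trial is flagged when either metric exceeds
    its threshold; the trial is removed when more than
    ``channel_fraction_limit`` of EEG channels are flagged. Surviving
    trials keep their flagged channels marked in ``bad_channels``.
    """
    eeg = epochs.montage.eeg_idx
    x = epochs.data[:, eeg, :]
    amp = x.max(axis=-1) - x.min(axis=-1)
    kurt = spstats.kurtosis(x, axis=-1, fisher=True, bias=True)

    thr_amp = float(np.median(amp) + k_sd * amp.std())
    thr_kurt = float(np.median(kurt) + k_sd * kurt.std())
    flagged = (amp > thr_amp) | (kurt > thr_kurt)
    frac = flagged.mean(axis=1)
    rejected = np.flatnonzero(frac > channel_fraction_limit)
    keep = np.flatnonzero(frac <= channel_fraction_limit)
    if len(keep) < 3:
        raise ValueError(f"only {len(keep)} trials survive rejection; need >= 3")

    out = epochs.select(keep)
    bad = out.bad_channels.copy()
    bad[:, eeg] |= flagged[keep]
    out.bad_channels = bad
    report = RejectionReport(
        amplitude=amp, kurtosis=kurt, flagged=flagged, rejected_trials=rejected,
        amp_threshold=thr_amp, kurt_threshold=thr_kurt, k_sd=k_sd,
        channel_fraction_limit=channel_fraction_limit,
    )
    return out, report


def common_average_reference(
    epochs: EpochSet, excluded_channels: np.ndarray | None = None
) -> EpochSet:
    """Re-reference every EEG channel to the mean of the included ones.

    ``excluded_channels`` defaults to the per-trial ``bad_channels``
    mask: excluded channels do not enter the average but are still
    re-referenced. EOG/ACCEL channels are untouched.
    """
    eeg = epochs.montage.eeg_idx
    if len(eeg) < 2:
        raise ValueError("common average reference needs at least 2 EEG channels")
    excl = epochs.bad_channels if excluded_channels is None else excluded_channels
    data = epochs.data.copy()
    for i in range(data.shape[0]):
        inc = eeg[~excl[i, eeg]]
        if len(inc) == 0:
            raise ValueError(f"trial {i}: every EEG channel excluded from the average")
        ref = data[i, inc, :].mean(axis=0)
        data[i, eeg, :] -= ref[None, :]
    out = EpochSet(
        data=data, alignment=epochs.alignment, window=epochs.window,
        sample_rate=epochs.sample_rate, montage=epochs.montage,
        meta=epochs.meta.copy(), bad_channels=epochs.bad_channels.copy(),
    )
    return out
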