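"""Synthetic ME/MI EEG cohort generator.

Sessions are built additively from interpretable sources, each projected
through a fixed scalp topography:

* an MRCP source — a slow negative ramp-and-return deflection peaking
  just before each trial's true movement onset, vertex-centred;
* mu and beta oscillators — band-limited Gaussian noise whose *power*
  envelope dips by the configured ERD depth around onset, centred over
  left centro-parietal sensorimotor cortex;
* blinks — low-frequency biphasic transients at Poisson times with a
  frontal-dominant topography, mirrored into the EOG channels;
* independent white sensor noise.

Topographies follow the average-reference forward convention (zero mean
over EEG channels), so common-average re-referencing downstream leaves
every source contribution unchanged. The accelerometer channel carries
a noisy mechanical step at the true onset in ME sessions and no step in
MI sessions. All hidden parameters are returned as :class:`GroundTruth`
so every downstream stage can be checked by parameter recovery.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import GenConfig
from .containers import CLASS_OF_MOVEMENT, EVENT_COLUMNS, GroundTruth, RawSession
from .montage import Montage, build_montage, default_eeg_labels, scalp_xy

# scalp anchor points (x, y) in metres, matched to the template head
_VERTEX = None  # taken from Cz
_SENSORIMOTOR_LEFT = None  # taken from CCP3h
_FRONTAL = None  # midpoint of Fp1/Fp2


def _gaussian_topography(xy: np.ndarray, center: np.ndarray, sigma: float) -> np.ndarray:
    d2 = np.sum((xy - center[None, :]) ** 2, axis=1)
    return np.exp(-d2 / (2 * sigma**2))


def _source_topography(
    montage: Montage, center_label_xy: np.ndarray, sigma: float, norm: str, roi: list[str] | None = None
) -> np.ndarray:
    """Zero-mean (over EEG) topography; full-length weight vector.

    Zero mean follows the average-reference forward convention, so
    common-average re-referencing downstream leaves each source's
    contribution unchanged. ``norm='peak'`` scales the maximum-|weight|
    EEG channel to 1 (mean-subtracted monopolar blob).
    ``norm='roi-min'`` builds a dipolar pattern — a positive lobe over
    the ROI, a broad compensating negative lobe over the contralateral
    frontal scalp — and scales the smallest-|weight| ROI channel to 1,
    so the source is never diluted below its nominal strength inside
    its ROI and no channel anywhere gets a runaway weight.
    """
    eeg = montage.eeg_idx
    xy = montage.positions[eeg]
    if norm == "peak":
        w = _gaussian_topography(xy, center_label_xy, sigma)
        w = w - w.mean()
        w = w / np.abs(w).max()
    elif norm == "roi-min":
        names = [montage.names[i] for i in eeg]
        ridx = [names.index(r) for r in roi if r in names]
        if not ridx:
            raise ValueError("no ROI channel present in montage")
        centroid = xy[ridx].mean(axis=0)
        # wide enough that the whole ROI sits on the lobe's flat top and
        # keeps one sign after mean subtraction
        w = _gaussian_topography(xy, centroid, sigma)
        w = w - w.mean()
        if np.any(np.sign(w[ridx]) != np.sign(w[ridx][0])):
            raise ValueError("topography changes sign inside its ROI; widen sigma")
        w = w / np.abs(w[ridx]).min()
    else:  # pragma: no cover
        raise ValueError(norm)
    full = np.zeros(len(montage))
    full[eeg] = w
    return full


@functools.lru_cache(maxsize=8)
def mrcp_template(sample_rate: float, ramp: float = 1.5, ret: float = 1.0,
                  band: tuple[float, float] = (0.3, 3.0), order: int = 4) -> tuple[np.ndarray, int]:
    """Band-projected ramp-and-return MRCP template, unit negative peak.

    Returns ``(template, peak_index)``; the template is constructed so
    its shape is (nearly) invariant under the MRCP analysis band filter,
    which makes the configured amplitude recoverable by the band-limited
    averaging pipeline. The raw shape is a half-cosine ramp of ``ramp``
    seconds to the negative peak 50 ms before onset and a ``ret`` second
    half-cosine return.
    """
    fs = sample_rate
    pad = 3.0
    t = np.arange(int(round((ramp + ret + 2 * pad) * fs))) / fs - pad - ramp
    # raw shape: peak at t = 0 (later shifted so the peak sits 50 ms pre-onset)
    v = np.zeros_like(t)
    rise = (t >= -ramp) & (t < 0)
    v[rise] = -0.5 * (1 - np.cos(np.pi * (t[rise] + ramp) / ramp))
    fall = (t >= 0) & (t < ret)
    v[fall] = -0.5 * (1 + np.cos(np.pi * t[fall] / ret))
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    for _ in range(40):  # project onto the band until the filter is ~idempotent
        v = sps.sosfiltfilt(sos, v)
        v = v / np.abs(v.min())
    peak = int(np.argmin(v))
    return v, peak


def _blink_kernel(sample_rate: float) -> np.ndarray:
    """Biphasic low-frequency blink transient, unit positive peak."""
    t = np.arange(int(round(0.8 * sample_rate))) / sample_rate - 0.25
    v = np.exp(-(t**2) / (2 * 0.06**2)) - 0.35 * np.exp(-((t - 0.18) ** 2) / (2 * 0.09**2))
    return v / v.max()


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                sample_rate: float, rms: float) -> np.ndarray:
    """Band-confined Gaussian noise.

    The rhythm is generated inside a band inset by 10% from each edge
    and filtered steeply (8th-order zero-phase), so adjacent analysis
    bands see essentially none of it — mu/beta cross-talk would
    otherwise bias ERD depth recovery.
    """
    x = rng.standard_normal(n)
    width = band[1] - band[0]
    inner = (band[0] + 0.1 * width, band[1] - 0.1 * width)
    sos = sps.butter(8, inner, btype="bandpass", fs=sample_rate, output="sos")
    x = sps.sosfiltfilt(sos, x)
    s = x.std()
    return x * (rms / s) if s > 0 else x


def _event_table(cfg: GenConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Randomised movement order with equal counts per type per block."""
    rows = []
    trial = 0
    per_block = list(np.repeat(cfg.movement_types, cfg.trials_per_movement_per_block))
    for block in range(cfg.blocks_per_session):
        order = rng.permutation(len(per_block))
        for j in order:
            s1 = cfg.session_padding + trial * cfg.trial_spacing + cfg.s1_time
            rows.append((trial, block, per_block[j], s1, s1 + (cfg.s2_time - cfg.s1_time)))
            trial += 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def _erd_profile(n: int, fs: float, onsets: np.ndarray, depths: np.ndarray,
                 recovery: float) -> np.ndarray:
    """Fractional power-suppression profile g(t)·depth over the session.

    Trapezoid per trial: linear decline from 0.9 s before onset, full
    depth held over onset ± 300 ms (wide enough that a 200 ms feature
    window plus 250 ms of power smoothing still reads the plateau),
    linear recovery complete ``recovery`` seconds after onset. The
    decline starts late enough that smoothing cannot bleed suppression
    into the −1.5..−1 s reference window.
    """
    g = np.zeros(n)
    t = np.arange(n) / fs
    for onset, d in zip(onsets, depths):
        lo = np.searchsorted(t, onset - 1.1)
        hi = np.searchsorted(t, onset + recovery + 0.2)
        tt = t[lo:hi] - onset
        prof = np.zeros_like(tt)
        fall = (tt >= -0.9) & (tt < -0.3)
        prof[fall] = (tt[fall] + 0.9) / 0.6
        prof[np.abs(tt) <= 0.3] = 1.0
        rec = (tt > 0.3) & (tt < recovery)
        prof[rec] = 1.0 - (tt[rec] - 0.3) / (recovery - 0.3)
        g[lo:hi] = np.maximum(g[lo:hi], prof * d)
    return g


@dataclass
class SubjectData:
    """One subject's pair of sessions plus the generator's hidden truth."""

    subject: str
    me: RawSession
    mi: RawSession
    truth: dict[str, GroundTruth]  # condition -> GroundTruth


def _session_rng(seed: int, subject_idx: int, condition: str) -> np.random.Generator:
    cond_code = {"ME": 0, "MI": 1}[condition]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(subject_idx, cond_code))
    )


def generate_session(
    cfg: GenConfig,
    subject_params: dict,
    condition: str,
    rng: np.random.Generator,
) -> tuple[RawSession, GroundTruth]:
    """Generate one continuous session and its ground truth.

    ``subject_params`` carries the subject label and the subject-level
    amplitude factor shared between that subject's ME and MI sessions.
    """
    errs = cfg.validate()
    if errs:
        raise ValueError("invalid GenConfig: " + "; ".join(errs))
    if condition not in ("ME", "MI"):
        raise ValueError(f"condition must be ME or MI, got {condition!r}")

    fs = cfg.sample_rate
    factor = float(subject_params.get("factor", 1.0))
    subject = str(subject_params.get("subject", "S01"))

    montage = build_montage(default_eeg_labels(cfg.n_eeg_channels), cfg.n_eog_channels)
    events = _event_table(cfg, rng)
    n_trials = len(events)
    duration = 2 * cfg.session_padding + n_trials * cfg.trial_spacing
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    # true onsets: S2 + positive delay, one per trial. MI has no overt
    # movement; its imagined onsets are modelled as locked to the
    # subject's habitual (ME class-mean) latency, which is exactly what
    # mean-imputation from ME trials can recover.
    classes = events["movement"].map(CLASS_OF_MOVEMENT).to_numpy()
    mi_latency = subject_params.get("mi_latency_by_class")
    if condition == "MI" and mi_latency is not None:
        delays = np.array([mi_latency[c] for c in classes])
    else:
        delays = cfg.onset_delay_mean + cfg.onset_delay_sd * rng.standard_normal(n_trials)
    delays = np.clip(delays, 0.05, None)
    onsets = events["s2_time"].to_numpy() + delays

    sig = np.zeros((len(montage), n))

    # --- MRCP source -------------------------------------------------
    true_amp = {
        cls: cfg.mrcp_amp[condition][cls] * factor for cls in cfg.mrcp_amp[condition]
    }
    if any(a != 0 for a in true_amp.values()):
        tpl, tpl_peak = mrcp_template(fs)
        src = np.zeros(n)
        for onset, cls in zip(onsets, classes):
            peak_idx = int(round((onset - 0.05) * fs))
            lo = peak_idx - tpl_peak
            hi = lo + len(tpl)
            a, b = max(lo, 0), min(hi, n)
            # tpl has unit *negative* peak, so scale by |amp| to keep the trough at amp
            src[a:b] += -true_amp[cls] * tpl[a - lo : b - lo]
        w_mrcp = _source_topography(montage, scalp_xy(["Cz"])[0], sigma=0.05, norm="peak")
        sig += w_mrcp[:, None] * src[None, :]

    # --- mu / beta oscillators with ERD envelopes --------------------
    recovery = 2.0 if condition == "ME" else 1.0
    depth_tables = {"mu": cfg.erd_depth_mu[condition], "beta": cfg.erd_depth_beta[condition]}
    true_depth: dict[str, dict[str, float]] = {"mu": {}, "beta": {}}
    topo_osc = {}
    from .montage import BETA_ROI, MU_ROI

    for band_name, band, rms, roi in (
        ("mu", cfg.mu_band, cfg.mu_rms, MU_ROI),
        ("beta", cfg.beta_band, cfg.beta_rms, BETA_ROI),
    ):
        depths_cls = {
            cls: float(np.clip(d * factor, 0.0, 0.95)) for cls, d in depth_tables[band_name].items()
        }
        true_depth[band_name] = depths_cls
        w = _source_topography(montage, None, sigma=0.1, norm="roi-min", roi=list(roi))
        topo_osc[band_name] = w
        if rms > 0:
            base = _band_noise(rng, n, band, fs, rms)
            g = _erd_profile(n, fs, onsets, np.array([depths_cls[c] for c in classes]), recovery)
            src = base * np.sqrt(1.0 - g)
            sig += w[:, None] * src[None, :]

    # --- blinks ------------------------------------------------------
    w_blink = _source_topography(
        montage, scalp_xy(["Fp1", "Fp2"]).mean(axis=0), sigma=0.045, norm="peak"
    )
    n_blinks = rng.poisson(cfg.blink_rate / 60.0 * duration) if cfg.blink_rate > 0 else 0
    blink_times = np.sort(rng.uniform(0, duration, size=n_blinks))
    if n_blinks:
        kern = _blink_kernel(fs)
        src = np.zeros(n)
        for bt in blink_times:
            lo = int(round(bt * fs))
            hi = min(lo + len(kern), n)
            src[lo:hi] += kern[: hi - lo]
        eeg_blink_amp = 0.8 * cfg.blink_amp
        sig += eeg_blink_amp * w_blink[:, None] * src[None, :]
        eog_gains = np.array([1.0, 0.85, 0.7])[: cfg.n_eog_channels]
        for g_i, ch in zip(eog_gains, montage.eog_idx):
            sig[ch] += cfg.blink_amp * g_i * src

    # --- sensor noise (EEG + EOG) ------------------------------------
    if cfg.noise_sd > 0:
        phys = np.concatenate([montage.eeg_idx, montage.eog_idx])
        sig[phys] += cfg.noise_sd * rng.standard_normal((len(phys), n))

    # --- accelerometer ------------------------------------------------
    acc = np.zeros(n)
    if condition == "ME":
        for onset in onsets:
            i0 = int(round(onset * fs))
            ir = max(int(round(cfg.accel_rise * fs)), 1)
            i1 = min(i0 + ir, n)
            ramp = 0.5 * (1 - np.cos(np.pi * np.arange(i1 - i0) / ir))
            acc[i0:i1] += cfg.accel_step * ramp
            hold_end = min(int(round((onset + 1.5) * fs)), n)
            acc[i1:hold_end] += cfg.accel_step
            fall = min(hold_end + int(round(0.3 * fs)), n)
            if fall > hold_end:
                acc[hold_end:fall] += cfg.accel_step * 0.5 * (
                    1 + np.cos(np.pi * np.arange(fall - hold_end) / (fall - hold_end))
                )
    if cfg.accel_noise_sd > 0:
        acc = acc + cfg.accel_noise_sd * rng.standard_normal(n)
    for ch in montage.accel_idx:
        sig[ch] = acc

    session = RawSession(
        subject=subject, condition=condition, signal=sig, sample_rate=fs,
        montage=montage, events=events,
    )
    truth = GroundTruth(
        subject=subject,
        condition=condition,
        mrcp_amp=true_amp,
        erd_depth=true_depth,
        onset_times=pd.DataFrame(
            {"trial": events["trial"], "movement": events["movement"], "onset_time": onsets}
        ),
        blink_topography=w_blink,
        mu_topography=topo_osc.get("mu"),
        beta_topography=topo_osc.get("beta"),
        subject_factor=factor,
        blink_times=blink_times,
    )
    return session, truth


def generate_cohort(cfg: GenConfig) -> list[SubjectData]:
    """Generate ``cfg.n_subjects`` paired ME/MI sessions.

    Per-subject amplitude factors are drawn once from a lognormal with
    the configured fractional spread and shared across both sessions;
    every session has its own independent RNG substream derived from the
    root seed, so regenerating a subset of subjects never perturbs the
    others.
    """
    if cfg.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    factor_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0xFAC,))
    )
    out = []
    for i in range(cfg.n_subjects):
        if cfg.between_subject_sd > 0:
            s = cfg.between_subject_sd
            factor = float(np.exp(s * factor_rng.standard_normal() - s**2 / 2))
        else:
            factor = 1.0
            factor_rng.standard_normal()  # keep the stream aligned
        params = {"subject": f"S{i + 1:02d}", "factor": factor}
        me, gt_me = generate_session(cfg, params, "ME", _session_rng(cfg.seed, i, "ME"))
        lat = gt_me.onset_times.assign(
            latency=gt_me.onset_times["onset_time"].to_numpy()
            - me.events["s2_time"].to_numpy(),
            cls=gt_me.onset_times["movement"].map(CLASS_OF_MOVEMENT),
        ).groupby("cls")["latency"].mean()
        params["mi_latency_by_class"] = lat.to_dict()
        mi, gt_mi = generate_session(cfg, params, "MI", _session_rng(cfg.seed, i, "MI"))
        out.append(SubjectData(params["subject"], me, mi, {"ME": gt_me, "MI": gt_mi}))
    return out
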