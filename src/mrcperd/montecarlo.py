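"""Monte Carlo nested trial-subset analysis of feature stability.

For each subject × condition × movement class, many independent
realizations of a *nested* chain of trial subsets are drawn: starting
from the retained trials, 10 random trials are removed at a time down
to 20, so each subset is a strict subset of the previous one. Features
are recomputed from the subset averages (never from per-trial
features), compared with the all-trials reference as absolute percent
differences, and summarised across subjects.

A chain is represented by a random permutation of the trial indices —
the size-``s`` subset is its first ``s`` elements, which is exactly the
successive-random-removal construction — so subset averages reduce to
prefix sums and the whole analysis is vectorised over realizations.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .config import ERDParams, MCConfig, MRCPParams
from .containers import MOVEMENT_CLASSES, EpochSet
from .preprocess import moving_average

REFERENCE_REALIZATION = -1  # marks the all-retained-trials rows


def cell_rng(seed: int, subject: str, condition: str, movement_class: str,
             stage: str = "mc") -> np.random.Generator:
    """Independent, composition-stable RNG substream for one cell."""
    key = zlib.crc32(f"{stage}|{subject}|{condition}|{movement_class}".encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def clipped_sizes(n_trials: int, cfg: MCConfig) -> list[int]:
    """Subset sizes feasible with ``n_trials`` retained trials."""
    if min(cfg.sizes) > n_trials:
        raise ValueError(
            f"minimum subset size {min(cfg.sizes)} exceeds the {n_trials} retained trials"
        )
    return [s for s in cfg.sizes if s <= n_trials]


def nested_subsets(
    trial_ids: np.ndarray, cfg: MCConfig, rng: np.random.Generator
) -> list[dict[int, np.ndarray]]:
    """Draw ``cfg.n_realizations`` nested chains of subsets of ``trial_ids``.

    Returns, per realization, a mapping size → trial-id array; within a
    chain each subset is a strict subset of the previous one.
    Deterministic given the generator state.
    """
    ids = np.asarray(trial_ids)
    sizes = clipped_sizes(len(ids), cfg)
    chains = []
    for _ in range(cfg.n_realizations):
        perm = rng.permutation(len(ids))
        chains.append({s: ids[perm[:s]] for s in sizes})
    return chains


def percent_difference(value: float, reference: float) -> float:
    """Absolute percent difference, ``100·|v − v_ref| / |v_ref|``."""
    if reference == 0:
        raise ZeroDivisionError("undefined percent difference: reference is 0")
    return 100.0 * abs((value - reference) / reference)


# --------------------------------------------------------------------
# vectorised subset features
# --------------------------------------------------------------------

def _permutations(n: int, n_real: int, rng: np.random.Generator) -> np.ndarray:
    return np.argsort(rng.random((n_real, n)), axis=1)


def _prefix_at(arr: np.ndarray, perms: np.ndarray, sizes: list[int]) -> np.ndarray:
    """Sums of ``arr`` rows over every permutation prefix; (R, K, d)."""
    g = arr[perms].astype(np.float64)  # (R, n, d)
    np.cumsum(g, axis=1, out=g)
    return g[:, np.asarray(sizes) - 1, :]


def _mrcp_subset_peaks(
    trace: np.ndarray, weight: np.ndarray, times: np.ndarray,
    perms: np.ndarray, sizes: list[int], params: MRCPParams,
) -> np.ndarray:
    """Peak feature for every (realization, size) from per-trial traces."""
    num = _prefix_at(trace * weight[:, None], perms, sizes)
    den = _prefix_at(weight[:, None], perms, sizes)[..., 0]
    if np.any(den == 0):
        raise ValueError("a subset has no usable trial at the MRCP channel")
    mean = num / den[..., None]  # (R, K, S)

    hw = params.peak_avg_width / 2.0
    lo, hi = params.peak_search
    searchable = (times >= max(lo, times[0] + hw)) & (times <= min(hi, times[-1] - hw))
    idx = np.flatnonzero(searchable)
    half = int(round(hw / (times[1] - times[0])))
    win = uniform_filter1d(mean, size=2 * half + 1, axis=-1, mode="nearest")
    seg = mean[..., idx]
    if params.polarity == "absolute":
        k = idx[np.argmax(np.abs(seg), axis=-1)]
    else:
        k = idx[np.argmin(seg, axis=-1)]
    return np.take_along_axis(win, k[..., None], axis=-1)[..., 0]


def _erd_subset_minima(
    num_scalars: np.ndarray, ref_scalars: np.ndarray, mask: np.ndarray,
    perms: np.ndarray, sizes: list[int],
) -> np.ndarray:
    """ERD-min for every (realization, size) from per-trial scalars.

    ``num_scalars``/``ref_scalars`` are (trials, roi_channels): the
    onset-window and reference-window means of each trial's smoothed
    power; ``mask`` zeroes bad trial×channel entries. The per-trial
    denominators cancel in the power ratio, so each channel's ERD is
    ``100·(Σ num / Σ ref − 1)``.
    """
    w = _prefix_at(num_scalars * mask, perms, sizes)  # (R, K, C)
    r = _prefix_at(ref_scalars * mask, perms, sizes)
    m = _prefix_at(mask, perms, sizes)
    usable = m > 0
    if not usable.any(axis=-1).all():
        raise ValueError("a subset has no usable ROI channel")
    with np.errstate(divide="ignore", invalid="ignore"):
        erd_c = 100.0 * (w / r - 1.0)
    erd_c[~usable] = np.nan
    return np.nanmean(erd_c, axis=-1)


def _mrcp_cell_inputs(ep: EpochSet, idx: np.ndarray, params: MRCPParams):
    times = ep.times
    hw = params.peak_avg_width / 2.0
    seg = (times >= params.peak_search[0] - hw - 1e-9) & (
        times <= params.peak_search[1] + hw + 1e-9
    )
    ch = ep.montage.index(params.channel)
    trace = ep.data[np.ix_(idx, [ch], np.flatnonzero(seg))][:, 0, :]
    weight = (~ep.bad_channels[idx, ch]).astype(float)
    return trace, weight, times[seg]


def _erd_cell_inputs(ep: EpochSet, idx: np.ndarray, params: ERDParams):
    times = ep.times
    rows = [ep.montage.index(c) for c in params.roi if c in ep.montage.names]
    if not rows:
        raise ValueError("no ROI channel in montage")
    power = ep.data[np.ix_(idx, rows)] ** 2  # (n, C, S)
    if params.power_smooth > 0:
        power = moving_average(power, int(round(params.power_smooth * ep.sample_rate)))
    hw = params.min_avg_width / 2.0
    win = (times >= -hw) & (times <= hw)
    r0, r1 = params.reference_window
    ref = (times >= r0) & (times < r1)
    num = power[..., win].mean(axis=-1)  # (n, C)
    rw = power[..., ref].mean(axis=-1)
    mask = (~ep.bad_channels[np.ix_(idx, rows)]).astype(float)
    return num, rw, mask


def mc_features(
    epochs_by_cell: dict[tuple[str, str], dict[str, EpochSet]],
    cfg: MCConfig,
    mrcp_params: MRCPParams,
    erd_mu: ERDParams,
    erd_beta: ERDParams,
    classes: list[str] | None = None,
) -> pd.DataFrame:
    """Feature table over (subject, condition, class, feature, size, realization).

    Features are recomputed from each subset's trial average; the
    all-retained-trials reference appears once per cell with
    ``realization == REFERENCE_REALIZATION``. Chains use one RNG
    substream per (subject, condition, class) derived from ``cfg.seed``.
    """
    classes = classes or MOVEMENT_CLASSES
    frames = []
    for (subject, condition), sets in sorted(epochs_by_cell.items()):
        for cls in classes:
            for feat, key, prm in (
                ("mrcp_peak", "mrcp", mrcp_params),
                ("erd_mu_min", "mu", erd_mu),
                ("erd_beta_min", "beta", erd_beta),
            ):
                ep = sets[key]
                idx = ep.class_indices(cls)
                n = idx.size
                sizes = clipped_sizes(n, cfg) + [n]  # + reference
                rng = cell_rng(cfg.seed, subject, condition, cls)
                perms = _permutations(n, cfg.n_realizations, rng)
                if feat == "mrcp_peak":
                    trace, weight, seg_times = _mrcp_cell_inputs(ep, idx, prm)
                    vals = _mrcp_subset_peaks(trace, weight, seg_times, perms, sizes, prm)
                else:
                    num, rw, mask = _erd_cell_inputs(ep, idx, prm)
                    vals = _erd_subset_minima(num, rw, mask, perms, sizes)
                k = len(sizes) - 1
                frame = pd.DataFrame({
                    "subject": subject, "condition": condition, "movement_class": cls,
                    "feature": feat,
                    "size": np.tile(sizes[:-1], cfg.n_realizations),
                    "realization": np.repeat(np.arange(cfg.n_realizations), k),
                    "value": vals[:, :k].ravel(),
                })
                ref_row = pd.DataFrame({
                    "subject": [subject], "condition": [condition],
                    "movement_class": [cls], "feature": [feat], "size": [n],
                    "realization": [REFERENCE_REALIZATION],
                    "value": [vals[0, k]],
                })
                frames.append(pd.concat([frame, ref_row], ignore_index=True))
    return pd.concat(frames, ignore_index=True)


def differences_table(mc_table: pd.DataFrame) -> pd.DataFrame:
    """Absolute percent difference of every subset feature vs its reference."""
    keys = ["subject", "condition", "movement_class", "feature"]
    refs = (
        mc_table[mc_table["realization"] == REFERENCE_REALIZATION]
        .set_index(keys)["value"]
    )
    sub = mc_table[mc_table["realization"] != REFERENCE_REALIZATION].copy()
    ref_vals = refs.loc[pd.MultiIndex.from_frame(sub[keys])].to_numpy()
    if np.any(ref_vals == 0):
        bad = sub.loc[ref_vals == 0, keys].drop_duplicates()
        raise ZeroDivisionError(f"zero reference feature in cells:\n{bad}")
    sub["pct_diff"] = 100.0 * np.abs((sub["value"].to_numpy() - ref_vals) / ref_vals)
    return sub.drop(columns="value")


def aggregate_differences(records: pd.DataFrame) -> pd.DataFrame:
    """Summarise percent differences: subject means, then across-subject quartiles.

    Returns one row per (feature, movement_class, condition, size) with
    the median and the 25th/75th percentiles of the per-subject mean
    differences; empty cells yield no row rather than zeros.
    """
    per_subj = (
        records.groupby(["feature", "movement_class", "condition", "size", "subject"])
        ["pct_diff"].mean().reset_index()
    )
    summary = (
        per_subj.groupby(["feature", "movement_class", "condition", "size"])["pct_diff"]
        .agg(median="median", q25=lambda v: v.quantile(0.25), q75=lambda v: v.quantile(0.75),
             n_subjects="count")
        .reset_index()
    )
    return summary
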