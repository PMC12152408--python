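"""End-to-end orchestration: synthesize → preprocess → onsets → features
→ Monte Carlo → statistics, with per-stage trial accounting.

Subjects are processed one at a time (a session's three band-filtered
epoch sets are sizeable), accumulating the feature, Monte Carlo and
per-channel tables; group statistics run on the concatenated tables at
the end. Every stage's RNG derives from the single root seed.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .containers import MOVEMENT_CLASSES, EpochSet, RawSession
from .features import compute_erd, compute_mrcp, extract_features, mrcp_peak
from .io import epoch_extract
from .montecarlo import aggregate_differences, differences_table, mc_features
from .onsets import detect_session_onsets, impute_mi_onsets
from .preprocess import bandpass, clean_session, common_average_reference, reject_artifacts
from .stats import mc_pvalue_profile, rm_anova_3way, topo_paired_t
from .synth import SubjectData, generate_cohort

log = logging.getLogger(__name__)


def _reject_by_class(epochs: EpochSet, cfg: RunConfig):
    """Amplitude/kurtosis rejection applied separately per movement class."""
    keep_parts = []
    rejected = {}
    for cls in MOVEMENT_CLASSES:
        idx = epochs.class_indices(cls)
        if idx.size == 0:
            continue
        sub = epochs.select(idx)
        kept, report = reject_artifacts(
            sub, k_sd=cfg.preproc.k_sd,
            channel_fraction_limit=cfg.preproc.channel_fraction_limit,
        )
        rejected[cls] = len(report.rejected_trials)
        keep_parts.append(kept.meta.assign(
            _bad=[kept.bad_channels[i] for i in range(kept.n_trials)]
        ))
    merged = pd.concat(keep_parts, ignore_index=True).sort_values("trial")
    bad_by_trial = {int(r["trial"]): r["_bad"] for _, r in merged.iterrows()}
    return sorted(bad_by_trial), bad_by_trial, rejected


def _band_epoch_set(
    session: RawSession, band: tuple[float, float], order: int,
    window: tuple[float, float], keep_trials: list[int], bad_by_trial: dict,
) -> EpochSet:
    """Filter the continuous recording, epoch around onset, CAR."""
    filt = session.signal.copy()
    phys = np.concatenate([session.montage.eeg_idx, session.montage.eog_idx])
    filt[phys] = bandpass(filt[phys], band[0], band[1], session.sample_rate, order=order)
    tmp = RawSession(
        subject=session.subject, condition=session.condition, signal=filt,
        sample_rate=session.sample_rate, montage=session.montage,
        events=session.events, onsets=session.onsets,
    )
    ep = epoch_extract(tmp, "onset", window)
    keep = [i for i in range(ep.n_trials) if int(ep.meta.loc[i, "trial"]) in set(keep_trials)]
    ep = ep.select(np.asarray(keep, dtype=int))
    ep.data = ep.data.astype(np.float32)
    bad = np.zeros((ep.n_trials, len(ep.montage)), dtype=bool)
    for i in range(ep.n_trials):
        bad[i] = bad_by_trial[int(ep.meta.loc[i, "trial"])]
    ep.bad_channels = bad
    return common_average_reference(ep)


def process_subject(
    data: SubjectData, cfg: RunConfig
) -> tuple[dict, pd.DataFrame]:
    """Clean, onset-align and epoch one subject's ME and MI sessions.

    Returns ``(epochs_by_cell, counts)``: the three aligned band epoch
    sets per condition, and per condition × class trial accounting
    (generated = retained + rejected + onset_failed).
    """
    epochs_by_cell: dict = {}
    count_rows = []
    me_onsets = None
    for condition in ("ME", "MI"):
        session = data.me if condition == "ME" else data.mi
        cleaned, _model = clean_session(session, cfg.preproc)

        if condition == "ME":
            onsets, n_failed = detect_session_onsets(cleaned, cfg.onset)
            me_onsets = onsets
        else:
            onsets = impute_mi_onsets(me_onsets, cleaned)
            n_failed = 0
        cleaned.onsets = onsets

        rej_epochs = epoch_extract(cleaned, "S1", cfg.preproc.reject_window)
        keep_trials, bad_by_trial, rejected = _reject_by_class(rej_epochs, cfg)
        with_onset = set(onsets["trial"].astype(int))
        onset_failed_kept = [t for t in keep_trials if t not in with_onset]
        keep_trials = [t for t in keep_trials if t in with_onset]

        cell = {}
        for key, band, order, window in (
            ("mrcp", cfg.mrcp.band, cfg.mrcp.filter_order, cfg.mrcp.window),
            ("mu", cfg.erd_mu.band, cfg.erd_mu.filter_order, cfg.erd_mu.window),
            ("beta", cfg.erd_beta.band, cfg.erd_beta.filter_order, cfg.erd_beta.window),
        ):
            cell[key] = _band_epoch_set(cleaned, band, order, window, keep_trials, bad_by_trial)
        epochs_by_cell[(data.subject, condition)] = cell

        ev = cleaned.events.copy()
        from .containers import pool_classes

        ev["movement_class"] = pool_classes(ev["movement"])
        kept_set = set(keep_trials)
        failed_set = set(onset_failed_kept)
        for cls in MOVEMENT_CLASSES:
            cls_trials = set(ev.loc[ev["movement_class"] == cls, "trial"].astype(int))
            count_rows.append({
                "subject": data.subject, "condition": condition, "movement_class": cls,
                "generated": len(cls_trials),
                "retained": len(cls_trials & kept_set),
                "rejected": rejected.get(cls, 0),
                "onset_failed": len(cls_trials & failed_set),
            })
        log.info("%s/%s: %d trials retained", data.subject, condition, len(keep_trials))
    counts = pd.DataFrame(count_rows)
    return epochs_by_cell, counts


def per_channel_features(
    epochs_by_cell: dict, cfg: RunConfig
) -> pd.DataFrame:
    """Full-trial-count feature value at every EEG channel (topography)."""
    rows = []
    for (subject, condition), sets in sorted(epochs_by_cell.items()):
        for cls in MOVEMENT_CLASSES:
            ep = sets["mrcp"]
            idx = ep.class_indices(cls)
            wf = compute_mrcp(ep, cfg.mrcp, idx)
            times = ep.times
            for ch_i in ep.montage.eeg_idx:
                prm = cfg.mrcp
                import dataclasses

                prm_ch = dataclasses.replace(prm, channel=ep.montage.names[ch_i])
                val = mrcp_peak(wf, times, ep.montage, prm_ch)
                rows.append({
                    "subject": subject, "condition": condition, "movement_class": cls,
                    "feature": "mrcp_peak", "channel": ep.montage.names[ch_i], "value": val,
                })
            for key, prm in (("mu", cfg.erd_mu), ("beta", cfg.erd_beta)):
                ep = sets[key]
                idx = ep.class_indices(cls)
                erd = compute_erd(ep, prm, idx)
                hw = prm.min_avg_width / 2.0
                mask = (ep.times >= -hw) & (ep.times <= hw)
                vals = np.nanmean(erd[:, mask], axis=1)
                for ch_i in ep.montage.eeg_idx:
                    rows.append({
                        "subject": subject, "condition": condition,
                        "movement_class": cls, "feature": f"erd_{key}_min",
                        "channel": ep.montage.names[ch_i], "value": float(vals[ch_i]),
                    })
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Outputs: ``features.tsv``, ``differences.tsv``, ``summaries.tsv``,
    ``pvalue_profiles.tsv``, ``anova.json``, ``topo.tsv`` and
    ``manifest.json`` with seeds and per-stage trial counts. Identical
    config + seed reproduce byte-identical tables.
    """
    errors = cfg.validate()
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=getattr(logging, cfg.log_level, logging.INFO))

    gen_cfg = cfg.gen
    if cfg.seed and gen_cfg.seed == 0:
        gen_cfg.seed = cfg.seed
    if cfg.seed and cfg.mc.seed == 0:
        cfg.mc.seed = cfg.seed + 1

    stage = "generate"
    try:
        cohort = generate_cohort(gen_cfg)
        feat_frames, mc_frames, topo_frames, count_frames = [], [], [], []
        for data in cohort:
            stage = f"process:{data.subject}"
            cells, counts = process_subject(data, cfg)
            count_frames.append(counts)
            stage = f"features:{data.subject}"
            feat_frames.append(extract_features(cells, cfg.mrcp, cfg.erd_mu, cfg.erd_beta))
            topo_frames.append(per_channel_features(cells, cfg))
            stage = f"montecarlo:{data.subject}"
            mc_frames.append(mc_features(cells, cfg.mc, cfg.mrcp, cfg.erd_mu, cfg.erd_beta))

        stage = "statistics"
        features = pd.concat(feat_frames, ignore_index=True)
        mc_table = pd.concat(mc_frames, ignore_index=True)
        topo = pd.concat(topo_frames, ignore_index=True)
        counts = pd.concat(count_frames, ignore_index=True)

        diffs = differences_table(mc_table)
        summaries = aggregate_differences(diffs)
        profiles = mc_pvalue_profile(mc_table, alpha=cfg.stats.alpha)
        anova = rm_anova_3way(features, standardize=cfg.stats.standardize_features)

        topo_tests = []
        for (feat, cls), grp in topo.groupby(["feature", "movement_class"]):
            me = grp[grp["condition"] == "ME"]
            mi = grp[grp["condition"] == "MI"]
            tt = topo_paired_t(me, mi)
            tt.insert(0, "movement_class", cls)
            tt.insert(0, "feature", feat)
            topo_tests.append(tt)
        topo_tests = pd.concat(topo_tests, ignore_index=True)

        stage = "write"
        features.to_csv(out / "features.tsv", sep="\t", index=False)
        diffs.to_csv(out / "differences.tsv", sep="\t", index=False)
        summaries.to_csv(out / "summaries.tsv", sep="\t", index=False)
        profiles.to_csv(out / "pvalue_profiles.tsv", sep="\t", index=False)
        topo_tests.to_csv(out / "topo.tsv", sep="\t", index=False)
        with open(out / "anova.json", "w") as fh:
            json.dump([r.as_dict() for r in anova], fh, indent=2)
        manifest = {
            "seed": cfg.seed,
            "gen_seed": gen_cfg.seed,
            "mc_seed": cfg.mc.seed,
            "n_subjects": gen_cfg.n_subjects,
            "sample_rate": gen_cfg.sample_rate,
            "counts": counts.to_dict(orient="records"),
            "totals": {
                "generated": int(counts["generated"].sum()),
                "retained": int(counts["retained"].sum()),
                "rejected": int(counts["rejected"].sum()),
                "onset_failed": int(counts["onset_failed"].sum()),
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return out
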