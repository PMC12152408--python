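"""Configuration dataclasses for every pipeline stage, plus validation.

Defaults reproduce the study conditions the package emulates: 15
subjects, 61 EEG + 3 EOG channels at 512 Hz, an S1–S2 paradigm with S1
at 0 s and S2 at 2 s, 10 blocks × 6 trials per movement per session
(60 trials per movement, 120 per pooled class), and an ME > MI
amplitude ordering. The *desk profile* (8 subjects, 16 channels,
256 Hz) is the scaled-down variant used for fast self-checks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .containers import MOVEMENT_CLASSES, MOVEMENT_TYPES


def _me_mi(me: dict[str, float], ratio: float) -> dict[str, dict[str, float]]:
    return {"ME": dict(me), "MI": {k: v * ratio for k, v in me.items()}}


@dataclass
class GenConfig:
    """Parameters of the synthetic session generator."""

    n_subjects: int = 15
    sample_rate: float = 512.0
    n_eeg_channels: int = 61
    n_eog_channels: int = 3
    blocks_per_session: int = 10
    trials_per_movement_per_block: int = 6
    movement_types: list[str] = field(default_factory=lambda: list(MOVEMENT_TYPES))
    s1_time: float = 0.0
    s2_time: float = 2.0
    trial_spacing: float = 10.0
    session_padding: float = 5.0
    # per-class source strengths; condition ratios give the ME > MI ordering
    mrcp_amp: dict[str, dict[str, float]] = field(
        default_factory=lambda: _me_mi(
            {"flexion/extension": -8.0, "pronation/supination": -6.5, "hand open/close": -5.0},
            0.6,
        )
    )
    erd_depth_mu: dict[str, dict[str, float]] = field(
        default_factory=lambda: _me_mi(
            {"flexion/extension": 0.45, "pronation/supination": 0.45, "hand open/close": 0.40},
            0.6,
        )
    )
    erd_depth_beta: dict[str, dict[str, float]] = field(
        default_factory=lambda: _me_mi(
            {"flexion/extension": 0.40, "pronation/supination": 0.40, "hand open/close": 0.35},
            0.6,
        )
    )
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (14.0, 30.0)
    mu_rms: float = 4.0  # µV, baseline rhythm amplitude at its peak channel
    beta_rms: float = 4.0
    onset_delay_mean: float = 0.5  # s after S2
    onset_delay_sd: float = 0.1
    blink_rate: float = 10.0  # events/min
    blink_amp: float = 120.0  # µV at the EOG mirror
    noise_sd: float = 2.0  # µV broadband sensor noise
    accel_step: float = 1.0  # glove/accelerometer units
    accel_rise: float = 0.05  # s, mechanical rise time of the step
    accel_noise_sd: float = 0.05
    between_subject_sd: float = 0.2  # fractional amplitude spread
    seed: int = 0

    @property
    def trials_per_movement(self) -> int:
        return self.blocks_per_session * self.trials_per_movement_per_block

    @property
    def n_trials(self) -> int:
        return self.trials_per_movement * len(self.movement_types)

    def validate(self) -> list[str]:
        errs = []
        nyq = self.sample_rate / 2.0
        if self.sample_rate <= 0:
            errs.append("sample_rate must be positive")
        if self.n_subjects < 1:
            errs.append("n_subjects must be >= 1")
        if self.blocks_per_session <= 0 or self.trials_per_movement_per_block <= 0:
            errs.append("trial counts must be positive")
        if self.s2_time <= self.s1_time:
            errs.append("S2 must follow S1")
        for name, band in (("mu_band", self.mu_band), ("beta_band", self.beta_band)):
            if not (0 < band[0] < band[1] < nyq):
                errs.append(f"{name} {band} must lie within (0, Nyquist={nyq:g})")
        for name, table in (
            ("erd_depth_mu", self.erd_depth_mu),
            ("erd_depth_beta", self.erd_depth_beta),
        ):
            for cond, per_class in table.items():
                for cls, d in per_class.items():
                    if not (0 <= d < 1):
                        errs.append(f"{name}[{cond}][{cls}]={d} outside [0, 1)")
        for cond, per_class in self.mrcp_amp.items():
            for cls, a in per_class.items():
                if a > 0:
                    errs.append(f"mrcp_amp[{cond}][{cls}]={a} must be <= 0 (negativity)")
        if self.blink_rate < 0 or self.noise_sd < 0 or self.accel_noise_sd < 0:
            errs.append("rates and noise SDs must be non-negative")
        if self.onset_delay_mean <= 0:
            errs.append("onset_delay_mean must be positive")
        if self.trial_spacing <= self.s2_time + self.onset_delay_mean:
            errs.append("trial_spacing too short for the paradigm timing")
        if self.seed < 0:
            errs.append("seed must be non-negative")
        missing = set(self.movement_types) - set(MOVEMENT_TYPES)
        if missing:
            errs.append(f"unknown movement types {sorted(missing)}")
        for table in (self.mrcp_amp, self.erd_depth_mu, self.erd_depth_beta):
            for cond in ("ME", "MI"):
                if set(table.get(cond, {})) != set(MOVEMENT_CLASSES):
                    errs.append(f"source tables must cover conditions ME/MI × {MOVEMENT_CLASSES}")
                    break
        return errs


def desk_profile(n_subjects: int = 8, seed: int = 0, **overrides) -> GenConfig:
    """Scaled-down study conditions for fast runs: 16 channels, 256 Hz."""
    kw = dict(
        n_subjects=n_subjects,
        sample_rate=256.0,
        n_eeg_channels=16,
        seed=seed,
    )
    kw.update(overrides)
    return GenConfig(**kw)


@dataclass
class PreprocParams:
    """Broadband filtering, SOBI ocular cleaning and trial rejection."""

    band: tuple[float, float] = (0.3, 100.0)
    filter_order: int = 4
    zero_phase: bool = True
    sobi_max_lag_s: float = 0.2  # lags 1..max_lag (in samples) for SOBI
    sobi_max_sweeps: int = 100
    ocular_low_freq: float = 5.0  # Hz: "slow" spectral cut for the classifier
    ocular_p_low: float = 0.55  # min fraction of power below the cut
    ocular_r_eog: float = 0.7  # min |corr| with an EOG channel
    ocular_f_front: float = 0.55  # min frontal concentration of the column
    k_sd: float = 5.0  # outlier threshold in pooled-SD units
    channel_fraction_limit: float = 0.25
    reject_window: tuple[float, float] = (-0.5, 7.0)  # s relative to S1

    def validate(self, sample_rate: float | None = None) -> list[str]:
        errs = []
        if not (0 < self.band[0] < self.band[1]):
            errs.append("filter band must satisfy 0 < low < high")
        # the high edge is clipped below Nyquist at run time; validation
        # only rejects bands that collapse entirely
        if sample_rate and self.band[0] >= self.filter_band(sample_rate)[1]:
            errs.append("filter band collapses below the recording's Nyquist")
        if self.k_sd <= 0:
            errs.append("k_sd must be positive")
        if not (0 < self.channel_fraction_limit <= 1):
            errs.append("channel_fraction_limit must be in (0, 1]")
        return errs

    def filter_band(self, sample_rate: float) -> tuple[float, float]:
        """Band clipped below Nyquist for low-rate (desk) recordings."""
        return (self.band[0], min(self.band[1], 0.45 * sample_rate))


@dataclass
class OnsetParams:
    threshold_k: float = 5.0  # baseline-SD units on the smoothed derivative
    smooth_width: float = 0.02  # s moving average
    search_window: float = 2.0  # s after S2
    refine_window: float = 0.25  # s back-search for the pre-step extremum

    def validate(self) -> list[str]:
        errs = []
        if self.threshold_k <= 0:
            errs.append("threshold_k must be positive")
        if self.smooth_width <= 0 or self.search_window <= 0:
            errs.append("onset windows must be positive")
        return errs


@dataclass
class MRCPParams:
    band: tuple[float, float] = (0.3, 3.0)
    filter_order: int = 4
    window: tuple[float, float] = (-2.5, 2.5)  # s re onset
    channel: str = "Cz"
    peak_search: tuple[float, float] = (-0.5, 0.0)  # s re onset
    peak_avg_width: float = 0.2  # s
    polarity: str = "negative"  # or "absolute"

    def validate(self) -> list[str]:
        errs = []
        if not (self.window[0] <= self.peak_search[0] < self.peak_search[1] <= self.window[1]):
            errs.append("peak search window must lie inside the epoch window")
        if self.peak_avg_width >= self.peak_search[1] - self.peak_search[0]:
            errs.append("peak averaging width must be smaller than the search window")
        if self.polarity not in ("negative", "absolute"):
            errs.append("polarity must be 'negative' or 'absolute'")
        return errs


@dataclass
class ERDParams:
    band: tuple[float, float] = (8.0, 13.0)
    band_name: str = "mu"
    filter_order: int = 4
    window: tuple[float, float] = (-2.5, 5.5)  # s re onset
    reference_window: tuple[float, float] = (-1.5, -1.0)
    roi: list[str] = field(default_factory=list)  # filled per band by default_erd_params
    min_avg_width: float = 0.2  # s, centred at onset
    power_smooth: float = 0.25  # s moving average on power; 0 disables

    def validate(self) -> list[str]:
        errs = []
        if not (self.window[0] <= self.reference_window[0] < self.reference_window[1] <= 0):
            errs.append("reference window must precede onset and lie in the epoch")
        if not self.roi:
            errs.append("ROI channel list must not be empty")
        if self.band[0] >= self.band[1] or self.band[0] <= 0:
            errs.append("ERD band must satisfy 0 < low < high")
        return errs


def default_erd_params(band_name: str) -> ERDParams:
    from .montage import BETA_ROI, MU_ROI

    if band_name == "mu":
        return ERDParams(band=(8.0, 13.0), band_name="mu", roi=list(MU_ROI))
    if band_name == "beta":
        return ERDParams(band=(14.0, 30.0), band_name="beta", roi=list(BETA_ROI))
    raise ValueError(f"unknown band {band_name!r}")


@dataclass
class MCConfig:
    """Monte Carlo nested trial-subset design."""

    n_realizations: int = 1000
    sizes: list[int] = field(default_factory=lambda: list(range(110, 19, -10)))
    reference_size: int = 120
    removal_block: int = 10
    seed: int = 0

    def validate(self) -> list[str]:
        errs = []
        if self.n_realizations < 1:
            errs.append("n_realizations must be >= 1")
        diffs = [a - b for a, b in zip(self.sizes, self.sizes[1:])]
        if any(d <= 0 for d in diffs):
            errs.append("subset sizes must be strictly descending")
        elif diffs and any(d != self.removal_block for d in diffs):
            errs.append("removal_block must equal the gap between consecutive sizes")
        if self.sizes and min(self.sizes) < 2:
            errs.append("minimum subset size must be >= 2")
        if self.seed < 0:
            errs.append("seed must be non-negative")
        return errs


@dataclass
class StatsParams:
    alpha: float = 0.05
    standardize_features: bool = True  # z-score each feature before the rmANOVA

    def validate(self) -> list[str]:
        return [] if 0 < self.alpha < 1 else ["alpha must be in (0, 1)"]


@dataclass
class RunConfig:
    """Everything one end-to-end pipeline run needs."""

    out_dir: Path = Path("mrcperd_run")
    gen: GenConfig = field(default_factory=GenConfig)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    onset: OnsetParams = field(default_factory=OnsetParams)
    mrcp: MRCPParams = field(default_factory=MRCPParams)
    erd_mu: ERDParams = field(default_factory=lambda: default_erd_params("mu"))
    erd_beta: ERDParams = field(default_factory=lambda: default_erd_params("beta"))
    mc: MCConfig = field(default_factory=MCConfig)
    stats: StatsParams = field(default_factory=StatsParams)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> list[str]:
        errs = []
        errs += [f"gen: {e}" for e in self.gen.validate()]
        errs += [f"preproc: {e}" for e in self.preproc.validate(self.gen.sample_rate)]
        errs += [f"onset: {e}" for e in self.onset.validate()]
        errs += [f"mrcp: {e}" for e in self.mrcp.validate()]
        errs += [f"erd_mu: {e}" for e in self.erd_mu.validate()]
        errs += [f"erd_beta: {e}" for e in self.erd_beta.validate()]
        errs += [f"mc: {e}" for e in self.mc.validate()]
        errs += [f"stats: {e}" for e in self.stats.validate()]
        if self.seed < 0:
            errs.append("seed must be non-negative")
        nyq = self.gen.sample_rate / 2
        for name, p in (("mrcp", self.mrcp), ("erd_mu", self.erd_mu), ("erd_beta", self.erd_beta)):
            if p.band[1] >= nyq:
                errs.append(f"{name}: band {p.band} exceeds Nyquist {nyq:g}")
        return errs


def _update_dataclass(obj, data: dict, path: str, errs: list[str]):
    names = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in names:
            errs.append(f"{path}: unknown key {key!r}")
            continue
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_dataclass(current, value, f"{path}.{key}", errs)
        elif isinstance(current, tuple) and isinstance(value, list):
            setattr(obj, key, tuple(value))
        elif isinstance(current, Path):
            setattr(obj, key, Path(value))
        else:
            setattr(obj, key, value)
    return obj


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a TOML file (flat tables per stage)."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    cfg = RunConfig()
    errs: list[str] = []
    _update_dataclass(cfg, data, "config", errs)
    if errs:
        raise ValueError("bad config: " + "; ".join(errs))
    return cfg
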