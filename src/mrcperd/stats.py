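"""Group statistics: paired t-tests, Monte Carlo p-value profiles, and a
fully within-subjects 3-way repeated-measures ANOVA with the
Greenhouse–Geisser sphericity correction.

The rmANOVA decomposes a complete balanced subject × A × B × C table
into every main effect and interaction, each tested against its own
subject-by-effect error term. Effects are parameterised by orthonormal
(Helmert) contrasts; Greenhouse–Geisser ε for an effect is
``(Σλ)² / (df · Σλ²)`` with λ the eigenvalues of the covariance of the
orthonormalised within-subject contrast scores, and the corrected
p-value uses ``ε·df`` numerator and ``ε·df·(n−1)`` denominator degrees
of freedom.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .montecarlo import REFERENCE_REALIZATION


@dataclass
class StatResult:
    """One test outcome."""

    name: str
    statistic: float
    df: tuple[float, float] | float
    p_value: float
    n: int
    epsilon: float | None = None  # GG ε when a sphericity correction applies
    p_uncorrected: float | None = None
    degenerate: bool = False

    def as_dict(self) -> dict:
        d = {"name": self.name, "statistic": self.statistic, "df": self.df,
             "p_value": self.p_value, "n": self.n}
        if self.epsilon is not None:
            d["epsilon"] = self.epsilon
            d["p_uncorrected"] = self.p_uncorrected
        if self.degenerate:
            d["degenerate"] = True
        return d


def paired_t(x: np.ndarray, y: np.ndarray, name: str = "paired_t") -> StatResult:
    """Two-sided paired t-test of matched vectors.

    ``t = mean(d) / (SD(d)/√n)`` with ``d = x − y`` and ``df = n − 1``;
    a zero-variance difference vector is flagged degenerate (p → 0 for
    a nonzero shift, p = 1 for an identically zero one).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t needs two equal-length 1-D vectors")
    n = len(x)
    if n < 2:
        raise ValueError("paired_t needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return StatResult(name, 0.0, n - 1, 1.0, n, degenerate=True)
        return StatResult(name, np.inf if d.mean() > 0 else -np.inf, n - 1, 0.0, n,
                          degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * spstats.t.sf(abs(t), n - 1)
    return StatResult(name, float(t), n - 1, float(p), n)


def mc_pvalue_profile(
    mc_table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Paired ME-vs-MI t-tests across Monte Carlo subsets.

    One test per (feature, movement class, size, realization) over the
    paired subjects; the profile reports the arithmetic mean p across
    realizations and the fraction with p ≤ α (the mean p is descriptive,
    not itself a calibrated test, so the exceedance fraction travels
    with it). Realizations missing either condition are skipped and
    counted.
    """
    sub = mc_table[mc_table["realization"] != REFERENCE_REALIZATION]
    wide = sub.pivot_table(
        index=["feature", "movement_class", "size", "realization", "subject"],
        columns="condition", values="value", aggfunc="first",
    )
    rows = []
    for (feat, cls, size), grp in wide.groupby(level=["feature", "movement_class", "size"]):
        pvals, skipped = [], 0
        for _, real_grp in grp.groupby(level="realization"):
            pair = real_grp.dropna()
            if len(pair) < 2 or "ME" not in pair.columns or "MI" not in pair.columns:
                skipped += 1
                continue
            pvals.append(paired_t(pair["ME"].to_numpy(), pair["MI"].to_numpy()).p_value)
        if not pvals:
            continue
        pvals = np.asarray(pvals)
        rows.append({
            "feature": feat, "movement_class": cls, "size": int(size),
            "mean_p": float(pvals.mean()),
            "frac_significant": float((pvals <= alpha).mean()),
            "n_realizations": len(pvals), "n_skipped": skipped,
            "mean_p_above_alpha": bool(pvals.mean() > alpha),
        })
    return pd.DataFrame(rows).sort_values(
        ["feature", "movement_class", "size"], ascending=[True, True, False]
    ).reset_index(drop=True)


# --------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------

def _helmert(k: int) -> np.ndarray:
    """Orthonormal contrast matrix, (k−1) × k rows orthogonal to 1."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1)
        h[i] /= np.linalg.norm(h[i])
    return h


def gg_epsilon(scores: np.ndarray) -> float:
    """Greenhouse–Geisser ε from orthonormal contrast scores (n × df).

    ε = (Σλ)² / (df·Σλ²) with λ the eigenvalues of the score covariance;
    bounded below by 1/df (the lower-bound correction) and above by 1.
    A singular covariance falls back to the lower bound.
    """
    n, df = scores.shape
    if df == 1:
        return 1.0
    s = np.cov(scores, rowvar=False, ddof=1)
    lam = np.linalg.eigvalsh(s)
    lam = np.clip(lam, 0, None)
    tot = lam.sum()
    if tot <= 0:
        return 1.0 / df
    eps = tot**2 / (df * np.sum(lam**2))
    return float(np.clip(eps, 1.0 / df, 1.0))


def rm_anova(values: np.ndarray, factor_names: list[str]) -> list[StatResult]:
    """Fully within-subjects ANOVA of ``values`` (subjects × k1 × … × km).

    Returns a StatResult per main effect and interaction, each GG
    corrected. The table must be complete (no NaN).
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing cells; the rmANOVA needs a complete table")
    n = values.shape[0]
    levels = values.shape[1:]
    m = len(levels)
    if len(factor_names) != m:
        raise ValueError("factor_names must match the number of factors")
    flat = values.reshape(n, -1)  # cells in C order of the factor axes

    contrasts = [_helmert(k) for k in levels]
    ones = [np.ones((1, k)) / np.sqrt(k) for k in levels]

    results = []
    for which in itertools.product(*[(False, True)] * m):
        if not any(which):
            continue
        mats = [contrasts[i] if w else ones[i] for i, w in enumerate(which)]
        c = mats[0]
        for mat in mats[1:]:
            c = np.kron(c, mat)
        scores = flat @ c.T  # (n, df_effect)
        df_e = scores.shape[1]
        mean = scores.mean(axis=0)
        ss_effect = n * float(mean @ mean)
        resid = scores - mean
        ss_error = float(np.sum(resid**2))
        df_err = df_e * (n - 1)
        name = " x ".join(fn for fn, w in zip(factor_names, which) if w)
        tol = 1e-12 * max(1.0, float(np.sum(flat**2)))
        if ss_error <= tol:
            degenerate = True
            f = 0.0 if ss_effect <= tol else np.inf
            p = 1.0 if ss_effect <= tol else 0.0
            results.append(StatResult(name, f, (df_e, df_err), p, n,
                                      epsilon=1.0, p_uncorrected=p, degenerate=degenerate))
            continue
        f = (ss_effect / df_e) / (ss_error / df_err)
        p_unc = float(spstats.f.sf(f, df_e, df_err))
        eps = gg_epsilon(scores)
        p_gg = float(spstats.f.sf(f, eps * df_e, eps * df_err))
        results.append(StatResult(name, float(f), (eps * df_e, eps * df_err), p_gg, n,
                                  epsilon=eps, p_uncorrected=p_unc))
    return results


def rm_anova_3way(
    features: pd.DataFrame,
    standardize: bool = True,
    value_col: str = "value",
) -> list[StatResult]:
    """3-way rmANOVA of the feature table: Feature × Class × Condition.

    ``features`` holds one value per subject × feature × movement class
    × condition (the full-trial-count features). Because the MRCP peak
    (µV) and the ERD minima (%) live on different scales, each feature
    is z-scored across all its values by default before entering the
    ANOVA; ``standardize=False`` uses raw values.
    """
    from .features import FEATURES
    from .containers import MOVEMENT_CLASSES

    df = features.copy()
    if standardize:
        def _z(v):
            s = v.std(ddof=1)
            return (v - v.mean()) / s if s > 0 else v - v.mean()
        df[value_col] = df.groupby("feature")[value_col].transform(_z)

    subjects = sorted(df["subject"].unique())
    shape = (len(subjects), len(FEATURES), len(MOVEMENT_CLASSES), 2)
    cube = np.full(shape, np.nan)
    pos_f = {f: i for i, f in enumerate(FEATURES)}
    pos_c = {c: i for i, c in enumerate(MOVEMENT_CLASSES)}
    pos_s = {s: i for i, s in enumerate(subjects)}
    pos_k = {"ME": 0, "MI": 1}
    for _, r in df.iterrows():
        cube[pos_s[r["subject"]], pos_f[r["feature"]],
             pos_c[r["movement_class"]], pos_k[r["condition"]]] = r[value_col]
    if np.isnan(cube).any():
        raise ValueError("incomplete subject × feature × class × condition table")
    return rm_anova(cube, ["Feature", "Class", "Condition"])


def topo_paired_t(
    me_values: pd.DataFrame, mi_values: pd.DataFrame, value_col: str = "value"
) -> pd.DataFrame:
    """Per-channel paired ME-vs-MI t-tests.

    Inputs are subject × channel tables (index subject, columns
    channels) or long frames with ``subject``/``channel`` columns. A
    channel missing for any subject in either condition is skipped (the
    count is reported in the ``skipped`` attribute). No
    multiple-comparison correction is applied.
    """
    def _wide(v):
        if {"subject", "channel"}.issubset(v.columns):
            return v.pivot(index="subject", columns="channel", values=value_col)
        return v

    me, mi = _wide(me_values), _wide(mi_values)
    channels = [c for c in me.columns if c in mi.columns]
    rows, skipped = [], 0
    for ch in channels:
        pair = pd.concat({"ME": me[ch], "MI": mi[ch]}, axis=1).dropna()
        if len(pair) < 2:
            skipped += 1
            continue
        res = paired_t(pair["ME"].to_numpy(), pair["MI"].to_numpy(), name=str(ch))
        rows.append({"channel": ch, "t": res.statistic, "p": res.p_value, "n": res.n})
    out = pd.DataFrame(rows, columns=["channel", "t", "p", "n"])
    out.attrs["skipped"] = skipped + (len(me.columns) - len(channels))
    return out
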