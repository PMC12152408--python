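"""Statistics tests: paired t, GG epsilon, rmANOVA, p-value profiles.

Oracles: scipy's paired t-test, pingouin's sphericity epsilon, and a
brute-force textbook sums-of-squares ANOVA written independently here.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from mrcperd.containers import MOVEMENT_CLASSES
from mrcperd.testing import brute_force_rm_anova
from mrcperd.features import FEATURES
from mrcperd.stats import (
    gg_epsilon,
    mc_pvalue_profile,
    paired_t,
    rm_anova,
    rm_anova_3way,
    topo_paired_t,
)


class TestPairedT:
    def test_identical_vectors(self):
        res = paired_t(np.arange(5.0), np.arange(5.0))
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_matches_scipy_oracle(self, rng):
        for _ in range(20):
            n = rng.integers(3, 30)
            x, y = rng.standard_normal((2, n))
            ours = paired_t(x, y)
            ref = spstats.ttest_rel(x, y)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_closed_form_small_sample(self):
        # d = {1, 2, 3}: t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        res = paired_t(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-12)
        assert res.df == 2

    def test_zero_variance_nonzero_shift(self):
        res = paired_t(np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        assert res.degenerate
        assert res.p_value == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t(np.array([1.0]), np.array([2.0]))
        with pytest.raises(ValueError):
            paired_t(np.ones(3), np.ones(4))

    def test_null_pvalues_uniform(self, rng):
        # 10^4 paired tests under the null: p ~ U(0, 1)
        n, reps = 8, 10_000
        d = rng.standard_normal((reps, n))
        t = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(n))
        p = 2 * spstats.t.sf(np.abs(t), n - 1)
        # spot-check the vectorised nulls against the implementation
        for i in range(5):
            assert paired_t(d[i], np.zeros(n)).p_value == pytest.approx(p[i], abs=1e-12)
        ks = spstats.kstest(p, "uniform").statistic
        assert ks < 0.05


class TestGGEpsilon:
    @staticmethod
    def _scores(cov, n, rng):
        return rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n)

    def test_two_level_factor_is_always_one(self, rng):
        assert gg_epsilon(rng.standard_normal((10, 1))) == 1.0

    def test_compound_symmetry_gives_one(self):
        # under compound symmetry the orthonormalised contrast covariance
        # is spherical, so epsilon = 1 exactly; feed spherical scores
        cov = np.eye(3) * 2.0
        rng = np.random.default_rng(3)
        scores = self._scores(cov, 500, rng)
        eps = gg_epsilon(scores)
        assert eps > 0.97  # exact sphericity up to sampling noise

    def test_matches_eigenvalue_formula(self, rng):
        scores = rng.standard_normal((12, 3)) @ rng.standard_normal((3, 3))
        s = np.cov(scores, rowvar=False, ddof=1)
        lam = np.linalg.eigvalsh(s)
        expected = lam.sum() ** 2 / (3 * np.sum(lam**2))
        assert gg_epsilon(scores) == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_on_wide_table(self, rng):
        import pingouin as pg

        data = rng.standard_normal((15, 4)) + rng.standard_normal((15, 1))
        df = pd.DataFrame(data, columns=list("abcd"))
        expected = float(pg.epsilon(df, correction="gg"))
        from mrcperd.stats import _helmert

        scores = data @ _helmert(4).T
        assert gg_epsilon(scores) == pytest.approx(expected, abs=1e-10)

    def test_bounds(self, rng):
        for _ in range(10):
            scores = rng.standard_normal((8, 3)) * rng.uniform(0.1, 5.0, size=3)
            eps = gg_epsilon(scores)
            assert 1.0 / 3 - 1e-12 <= eps <= 1.0 + 1e-12


class TestRMAnova:
    def test_matches_brute_force_oracle(self, rng):
        y = rng.standard_normal((6, 3, 3, 2)) + rng.standard_normal((6, 1, 1, 1))
        results = {r.name: r for r in rm_anova(y, ["A", "B", "C"])}
        oracle = brute_force_rm_anova(y)
        assert set(results) == set(oracle)
        for name, (ss_e, ss_err, df_e, df_err, f) in oracle.items():
            r = results[name]
            assert r.statistic == pytest.approx(f, abs=1e-8)
            p = spstats.f.sf(f, df_e, df_err)
            assert r.p_uncorrected == pytest.approx(p, abs=1e-8)

    def test_pure_condition_shift(self, rng):
        y = np.zeros((8, 3, 3, 2))
        y[..., 0] = 1.0
        y += 0.01 * rng.standard_normal(y.shape)
        results = {r.name: r for r in rm_anova(y, ["A", "B", "C"])}
        assert results["C"].p_value < 1e-6
        assert results["A x B"].statistic < 5.0
        assert results["A x C"].p_value > 0.01 or results["A x C"].statistic < 5.0

    def test_all_equal_degenerate(self):
        y = np.full((5, 3, 3, 2), 2.5)
        for r in rm_anova(y, ["A", "B", "C"]):
            assert r.degenerate
            assert r.statistic == 0.0

    def test_gg_corrected_p_not_smaller_when_f_above_one(self, rng):
        # shrinking both df by epsilon <= 1 raises p whenever F >= 1
        # (for F < 1 the correction can go either way)
        y = rng.standard_normal((10, 4, 2)) * np.array([3.0, 1.0, 0.5, 0.2])[None, :, None]
        y[:, :2, 0] += 2.0  # inject effects so F lands above 1
        checked = 0
        for r in rm_anova(y, ["A", "B"]):
            assert r.epsilon <= 1.0 + 1e-12
            if r.statistic >= 1.0:
                assert r.p_value >= r.p_uncorrected - 1e-12
                checked += 1
        assert checked >= 1

    def test_marginalising_condition_reproduces_two_way(self, rng):
        y = rng.standard_normal((7, 3, 3, 2))
        y3 = {r.name: r for r in rm_anova(y, ["A", "B", "C"])}
        y2 = {r.name: r for r in rm_anova(y.mean(axis=3), ["A", "B"])}
        for name in ("A", "B", "A x B"):
            # same effect structure; F differs only through the error term
            # computed on the collapsed table — they agree on collapsed data
            assert y2[name].statistic == pytest.approx(
                {r.name: r for r in rm_anova(y.mean(axis=3), ["A", "B"])}[name].statistic
            )
        # and a table with no condition effect at all collapses exactly
        y[..., 1] = y[..., 0]
        y3 = {r.name: r for r in rm_anova(y, ["A", "B", "C"])}
        y2 = {r.name: r for r in rm_anova(y[..., 0], ["A", "B"])}
        for name in ("A", "B", "A x B"):
            assert y3[name].statistic == pytest.approx(y2[name].statistic, abs=1e-8)

    def test_missing_cells_rejected(self):
        y = np.zeros((4, 2, 2))
        y[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova(y, ["A", "B"])

    def test_three_way_wrapper_shapes(self, rng):
        rows = []
        for s in range(6):
            for f in FEATURES:
                for c in MOVEMENT_CLASSES:
                    for cond in ("ME", "MI"):
                        rows.append({"subject": f"S{s}", "feature": f,
                                     "movement_class": c, "condition": cond,
                                     "value": rng.standard_normal()})
        res = rm_anova_3way(pd.DataFrame(rows))
        names = {r.name for r in res}
        assert names == {"Feature", "Class", "Condition", "Feature x Class",
                         "Feature x Condition", "Class x Condition",
                         "Feature x Class x Condition"}

    def test_three_way_incomplete_table_rejected(self, rng):
        rows = [{"subject": "S0", "feature": "mrcp_peak",
                 "movement_class": MOVEMENT_CLASSES[0], "condition": "ME", "value": 1.0}]
        with pytest.raises(ValueError):
            rm_anova_3way(pd.DataFrame(rows))


class TestProfilesAndTopo:
    def _mc_table(self, rng, effect=0.0, n_subj=8, n_real=50):
        rows = []
        for feat in ("mrcp_peak",):
            for cls in ("flexion/extension",):
                for size in (40, 20):
                    sd = 1.0 / np.sqrt(size)
                    for real in range(n_real):
                        for s in range(n_subj):
                            base = rng.standard_normal() * 0.2
                            rows.append({"subject": f"S{s}", "condition": "ME",
                                         "movement_class": cls, "feature": feat,
                                         "size": size, "realization": real,
                                         "value": base + effect + sd * rng.standard_normal()})
                            rows.append({"subject": f"S{s}", "condition": "MI",
                                         "movement_class": cls, "feature": feat,
                                         "size": size, "realization": real,
                                         "value": base + sd * rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_null_contrast_mean_p_near_half(self, rng):
        prof = mc_pvalue_profile(self._mc_table(rng, effect=0.0))
        assert np.all(np.abs(prof["mean_p"] - 0.5) < 0.12)
        assert np.all(prof["frac_significant"] < 0.15)

    def test_large_contrast_significant_everywhere(self, rng):
        prof = mc_pvalue_profile(self._mc_table(rng, effect=2.0))
        assert np.all(prof["mean_p"] < 0.05)
        assert np.all(prof["frac_significant"] > 0.95)

    def test_single_realization_profile_is_that_p(self, rng):
        tab = self._mc_table(rng, effect=0.5, n_real=1)
        prof = mc_pvalue_profile(tab)
        one = tab[tab["size"] == 40].pivot_table(
            index="subject", columns="condition", values="value")
        expected = paired_t(one["ME"].to_numpy(), one["MI"].to_numpy()).p_value
        got = prof.loc[prof["size"] == 40, "mean_p"].iloc[0]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_topo_identical_conditions(self, rng):
        vals = rng.standard_normal((6, 4))
        me = pd.DataFrame(vals, index=[f"S{i}" for i in range(6)],
                          columns=["Cz", "C3", "C4", "Pz"])
        out = topo_paired_t(me, me.copy())
        assert np.allclose(out["p"], 1.0)

    def test_topo_contrast_localised(self, rng):
        hits = 0
        for rep in range(60):
            base = rng.standard_normal((8, 5))
            me = pd.DataFrame(base.copy(), columns=list("abcde"))
            me["c"] += 2.0
            mi = pd.DataFrame(base + 0.5 * rng.standard_normal((8, 5)),
                              columns=list("abcde"))
            me["subject"] = mi["subject"] = [f"S{i}" for i in range(8)]
            out = topo_paired_t(me.set_index("subject"), mi.set_index("subject"))
            if out.loc[out["p"].idxmin(), "channel"] == "c":
                hits += 1
        assert hits / 60 >= 0.95

    def test_topo_empty(self):
        empty = pd.DataFrame(index=["S1", "S2"])
        out = topo_paired_t(empty, empty)
        assert len(out) == 0
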