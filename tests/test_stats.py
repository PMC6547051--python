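"""Stepwise selection, LOOCV, permutation test, partial correlation, ANOVA."""

import numpy as np
import pandas as pd
import pytest

from betalearn.stats import (
    loocv_predict,
    partial_correlation,
    permutation_test,
    rm_anova,
    stepwise_regression,
    zscore_table,
)


def _df(X):
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class TestZscore:
    def test_closed_form(self):
        out = zscore_table(pd.DataFrame({"a": [1.0, 2.0, 3.0]}))
        assert np.allclose(out["a"], [-1, 0, 1])

    def test_idempotent(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 3)), columns=list("abc"))
        once = zscore_table(X)
        twice = zscore_table(once)
        assert np.allclose(once, twice)

    def test_matches_manual(self, rng):
        X = pd.DataFrame(rng.standard_normal((38, 22)))
        X.columns = [f"c{i}" for i in range(22)]
        out = zscore_table(X)
        manual = (X - X.mean()) / X.std(ddof=1)
        assert np.allclose(out, manual)

    def test_constant_column_named(self):
        X = pd.DataFrame({"good": [1.0, 2, 3], "flat": [5.0, 5, 5]})
        with pytest.raises(ValueError, match="flat"):
            zscore_table(X)


class TestStepwise:
    def test_exact_predictor_found(self, rng):
        X = rng.standard_normal((38, 10))
        y = X[:, 4].copy()
        m = stepwise_regression(_df(X), y)
        assert m.selected == ["x4"]
        assert m.r_squared == pytest.approx(1.0, abs=1e-10)
        assert m.beta[0] == pytest.approx(1.0, abs=1e-8)

    def test_matches_exhaustive_best_subset_on_strong_signal(self, rng):
        # two independent true predictors; compare the selected set against
        # an exhaustive search over all subsets scored by adjusted fit
        X = rng.standard_normal((60, 6))
        y = 1.2 * X[:, 1] - 0.9 * X[:, 3] + 0.1 * rng.standard_normal(60)
        m = stepwise_regression(_df(X), y)
        assert set(m.selected) == {"x1", "x3"}

    def test_weak_single_candidate_empty_model(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)  # independent; p almost surely > .05
        # force the specific example: correlation with p ~ 0.2
        while True:
            r = np.corrcoef(x, y)[0, 1]
            from scipy import stats as sps
            t = abs(r) * np.sqrt(38 / (1 - r**2))
            p = 2 * sps.t.sf(t, 38)
            if p > 0.15:
                break
            y = rng.standard_normal(40)
        m = stepwise_regression(_df(x[:, None]), y)
        assert m.selected == []

    def test_alpha_enter_zero_always_empty(self, rng):
        X = rng.standard_normal((30, 5))
        y = X[:, 0]
        m = stepwise_regression(_df(X), y, alpha_enter=0.0)
        assert m.selected == []

    def test_null_entry_rate_near_familywise_alpha(self, rng):
        # with 10 independent null regressors, P(any entry) is roughly
        # 1 - 0.95^10 = 0.40; allow a generous binomial band
        hits = 0
        n_rep = 150
        for _ in range(n_rep):
            X = rng.standard_normal((38, 10))
            y = rng.standard_normal(38)
            if stepwise_regression(_df(X), y).selected:
                hits += 1
        assert 0.25 < hits / n_rep < 0.55


class TestLOOCV:
    def test_perfect_linear_recovery(self, rng):
        X = rng.standard_normal((20, 4))
        y = 2.0 * X[:, 0]
        res = loocv_predict(_df(X), y)
        assert res.r_actual_pred == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(res.predicted, y, atol=1e-6)

    def test_null_r_rarely_large_positive(self, rng):
        """Under the null, LOOCV r is negatively biased (the training-fold
        mean anti-correlates with the held-out value), so significance must
        come from the permutation distribution; large positive r must
        nevertheless stay rare."""
        rs = []
        for _ in range(60):
            X = rng.standard_normal((20, 5))
            y = rng.standard_normal(20)
            rs.append(loocv_predict(_df(X), y).r_actual_pred)
        assert np.mean(rs) < 0.1          # no optimistic bias
        assert np.quantile(rs, 0.95) < 0.6  # strong-looking fits are rare

    def test_refit_policy_less_optimistic_on_average(self, rng):
        diffs = []
        for _ in range(40):
            X = rng.standard_normal((25, 8))
            y = 0.5 * X[:, 0] + rng.standard_normal(25)
            ri = loocv_predict(_df(X), y, policy="refit_inside_folds").r_actual_pred
            rf = loocv_predict(_df(X), y, policy="fixed_model").r_actual_pred
            diffs.append(rf - ri)
        assert np.mean(diffs) > 0

    def test_affine_invariance_of_r(self, rng):
        X = rng.standard_normal((22, 4))
        y = 0.8 * X[:, 1] + 0.3 * rng.standard_normal(22)
        r1 = loocv_predict(_df(X), y).r_actual_pred
        r2 = loocv_predict(_df(X), 5.0 - 2.0 * y).r_actual_pred
        assert abs(abs(r2) - abs(r1)) < 1e-9

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError):
            loocv_predict(_df(rng.standard_normal((4, 2))), np.arange(4.0))


class TestPermutation:
    def test_floor_when_signal_dominates(self, rng):
        X = rng.standard_normal((25, 4))
        y = X[:, 0]
        res = permutation_test(_df(X), y, n_iter=100, seed=9)
        assert res.permutation_p == pytest.approx(1 / 101)

    def test_determinism(self, rng):
        X = rng.standard_normal((20, 4))
        y = 0.5 * X[:, 0] + rng.standard_normal(20)
        p1 = permutation_test(_df(X), y, n_iter=30, seed=5).permutation_p
        p2 = permutation_test(_df(X), y, n_iter=30, seed=5).permutation_p
        assert p1 == p2

    def test_p_floor_property(self, rng):
        X = rng.standard_normal((15, 3))
        y = rng.standard_normal(15)
        res = permutation_test(_df(X), y, n_iter=20, seed=2)
        assert res.permutation_p >= 1 / 21
        assert res.permutation_p <= 1.0


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self, rng):
        x, y = rng.standard_normal((2, 30))
        r, p = partial_correlation(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        n = 38
        z = rng.standard_normal((n, 2))
        x = z[:, 0] + rng.standard_normal(n)
        y = 0.5 * z[:, 0] - z[:, 1] + rng.standard_normal(n)
        r, p = partial_correlation(x, y, z)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-val"
        assert p == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-10)

    def test_constant_outcome_errors(self):
        with pytest.raises(ValueError):
            partial_correlation(np.arange(10.0), np.arange(10.0),
                                np.arange(10.0)[:, None])

    def test_rank_deficient_covariates(self, rng):
        x, y = rng.standard_normal((2, 20))
        Z = np.ones((20, 2))
        with pytest.raises(ValueError):
            partial_correlation(x, y, Z)


def _long_data(Y, glev, w1lev, w2lev=None):
    rows = []
    g, n = Y.shape[0], Y.shape[1]
    for gi in range(g):
        for si in range(n):
            sid = f"{glev[gi]}_{si}"
            for ai in range(Y.shape[2]):
                if w2lev is None:
                    rows.append(dict(subject=sid, group=glev[gi],
                                     w1=w1lev[ai], y=Y[gi, si, ai]))
                else:
                    for bi in range(Y.shape[3]):
                        rows.append(dict(subject=sid, group=glev[gi],
                                         w1=w1lev[ai], w2=w2lev[bi],
                                         y=Y[gi, si, ai, bi]))
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_within_levels_zero_effect(self, rng):
        base = rng.standard_normal((2, 5, 1, 1))
        Y = np.repeat(base, 3, axis=2)[:, :, :, 0]
        data = _long_data(Y, ["a", "b"], ["w1", "w2", "w3"])
        res = rm_anova(data, "y", "subject", "group", ["w1"])
        row = res.table[res.table.effect == "w1"].iloc[0]
        assert row.F == pytest.approx(0.0, abs=1e-20)

    def test_two_level_factor_no_correction(self, rng):
        Y = rng.standard_normal((2, 6, 2))
        data = _long_data(Y, ["a", "b"], ["x", "y"])
        res = rm_anova(data, "y", "subject", "group", ["w1"])
        assert res.sphericity["w1"]["applied"] is False
        assert not res.table.gg_corrected.any()

    def test_matches_pingouin_mixed_anova(self, rng):
        import pingouin as pg

        Y = rng.standard_normal((2, 8, 3)) + np.array([0.0, 0.4, 1.0])
        data = _long_data(Y, ["young", "elderly"], ["Pre", "Post1", "Post2"])
        res = rm_anova(data, "y", "subject", "group", ["w1"])
        ref = pg.mixed_anova(data, dv="y", within="w1", subject="subject",
                             between="group", correction=False)
        for eff, ref_name in (("group", "group"), ("w1", "w1"),
                              ("group*w1", "Interaction")):
            mine = res.table[res.table.effect == eff].iloc[0]
            theirs = ref[ref.Source == ref_name].iloc[0]
            assert mine.F == pytest.approx(float(theirs.F), rel=1e-8)
            assert mine.np2 == pytest.approx(float(theirs.np2), rel=1e-8)

    def test_gg_correction_engages_iff_mauchly_rejects(self, rng):
        # strongly heterogeneous level variances violate sphericity
        n = 12
        Y = np.empty((2, n, 4))
        Y[..., 0] = rng.standard_normal((2, n)) * 0.1
        Y[..., 1] = rng.standard_normal((2, n)) * 0.1
        Y[..., 2] = rng.standard_normal((2, n)) * 0.1
        Y[..., 3] = rng.standard_normal((2, n)) * 8.0 + 1.0
        data = _long_data(Y, ["a", "b"], ["l1", "l2", "l3", "l4"])
        res = rm_anova(data, "y", "subject", "group", ["w1"])
        sph = res.sphericity["w1"]
        assert sph["applied"] == (sph["p"] < 0.05)
        corrected = res.table[res.table.effect == "w1"].iloc[0].gg_corrected
        assert corrected == sph["applied"]

    def test_unbalanced_design_rejected(self, rng):
        Y = rng.standard_normal((2, 5, 2))
        data = _long_data(Y, ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError):
            rm_anova(data.iloc[:-1], "y", "subject", "group", ["w1"])

    def test_posthoc_present_for_significant_effect(self, rng):
        Y = rng.standard_normal((2, 10, 3)) * 0.3 + np.array([0.0, 1.0, 2.5])
        data = _long_data(Y, ["a", "b"], ["l1", "l2", "l3"])
        res = rm_anova(data, "y", "subject", "group", ["w1"])
        assert res.posthoc is not None
        assert (res.posthoc.effect == "w1").sum() == 3  # all pairwise levels
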