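import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from frailkit.survival import (
    ahr_fit,
    auc_t,
    cox_fit,
    fi_quartile_groups,
    km_curve,
    km_logrank,
    prentice_weights,
    schoenfeld_test,
)


def _exp_cohort(gen, n=400, beta=0.7, censor_scale=1.5):
    x = gen.normal(size=n)
    T = gen.exponential(1 / np.exp(beta * x))
    C = gen.exponential(censor_scale, n)
    return pd.DataFrame({"t": np.minimum(T, C), "e": (T <= C).astype(int), "x": x})


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(1, 60)
        curve = km_curve(t, np.ones(60, dtype=int))
        for _, row in curve.iloc[1:].iterrows():
            empirical = (t > row["time"]).mean()
            assert row["survival"] == pytest.approx(empirical, abs=1e-12)

    def test_single_event_drop(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        e = np.array([0, 0, 1, 0, 0])
        curve = km_curve(t, e)
        at3 = curve.loc[curve["time"] == 3.0, "survival"].iloc[0]
        assert at3 == pytest.approx(1 - 1 / 3)  # 3 at risk when the event occurs

    def test_n_subjects_one_event_at_t(self):
        n = 8
        t = np.concatenate([[1.0], np.full(n - 1, 5.0)])
        e = np.concatenate([[1], np.zeros(n - 1, dtype=int)])
        curve = km_curve(t, e)
        assert curve.loc[curve["time"] == 1.0, "survival"].iloc[0] == pytest.approx(1 - 1 / n)

    def test_survival_monotone_from_one(self, rng):
        df = _exp_cohort(rng, n=100)
        curve = km_curve(df["t"], df["e"])
        s = curve["survival"].to_numpy()
        assert s[0] == 1.0 or curve["time"].iloc[0] > 0
        assert np.all(np.diff(s) <= 1e-12)

    def test_logrank_groups_and_quartiles(self, rng):
        df = _exp_cohort(rng, n=200)
        groups = fi_quartile_groups(df["x"].to_numpy())
        out = km_logrank(df["t"], df["e"], groups)
        assert set(out.curves) == {1, 2, 3, 4}
        assert out.logrank_df == 3
        assert out.logrank_p < 0.05  # x drives the hazard

    def test_zero_events_raise(self):
        with pytest.raises(ValueError):
            km_logrank(np.ones(10), np.zeros(10, dtype=int), np.repeat([0, 1], 5))

    def test_logrank_null_calibration_quick(self):
        gen = np.random.default_rng(17)
        rej = 0
        n_sims = 150
        for _ in range(n_sims):
            t = gen.exponential(1, 120)
            c = gen.exponential(1.5, 120)
            g = gen.integers(0, 2, 120)
            out = km_logrank(np.minimum(t, c), (t <= c).astype(int), g)
            rej += out.logrank_p < 0.05
        assert 0.01 <= rej / n_sims <= 0.11


class TestQuartiles:
    def test_ties_assigned_to_lower_quartile(self):
        fi = np.array([1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = fi_quartile_groups(fi)
        cut1 = np.quantile(fi, 0.25)
        assert all(labels[fi <= cut1] == 1)

    def test_rank_invariance_under_monotone_transform(self, rng):
        fi = rng.uniform(size=101)
        np.testing.assert_array_equal(fi_quartile_groups(fi), fi_quartile_groups(np.exp(3 * fi)))


class TestCoxFit:
    def test_null_covariate_ci_covers_one(self, rng):
        df = _exp_cohort(rng, n=300, beta=0.0)
        fit = cox_fit(df, "t", "e", ["x"])
        ci = fit.confint()
        assert ci.loc["x", "lower"] < 1.0 < ci.loc["x", "upper"]

    def test_two_group_hr2_recovery(self):
        gen = np.random.default_rng(23)
        n = 2000
        g = gen.integers(0, 2, n)
        T = gen.exponential(1 / np.exp(np.log(2.0) * g))
        df = pd.DataFrame({"t": T, "e": np.ones(n, dtype=int), "x": g.astype(float)})
        fit = cox_fit(df, "t", "e", ["x"])
        assert abs(fit.params["x"] - np.log(2.0)) < 3 * fit.se["x"]

    def test_matches_brute_force_partial_likelihood_newton(self, rng):
        df = _exp_cohort(rng, n=150).sort_values("t").reset_index(drop=True)
        fit = cox_fit(df, "t", "e", ["x"])
        # independent oracle: explicit partial likelihood, scalar Newton
        t, e, x = df["t"].to_numpy(), df["e"].to_numpy(), df["x"].to_numpy()

        def derivs(beta):
            ll = s = h = 0.0
            for i in range(len(t)):
                if e[i] != 1:
                    continue
                risk = t >= t[i]
                w = np.exp(beta * x[risk])
                s0 = w.sum()
                s1 = (w * x[risk]).sum()
                s2 = (w * x[risk] ** 2).sum()
                ll += beta * x[i] - np.log(s0)
                s += x[i] - s1 / s0
                h += s2 / s0 - (s1 / s0) ** 2
            return ll, s, h

        beta = 0.0
        for _ in range(50):
            _, s, h = derivs(beta)
            step = s / h
            beta += step
            if abs(step) < 1e-12:
                break
        assert fit.params["x"] == pytest.approx(beta, abs=1e-6)

    def test_matches_lifelines_with_ties(self, rng):
        from lifelines import CoxPHFitter

        df = _exp_cohort(rng, n=300)
        df["t"] = np.round(df["t"], 1).clip(lower=0.1)  # induce ties
        fit = cox_fit(df, "t", "e", ["x"], ties="efron")
        cph = CoxPHFitter()
        cph.fit(df, "t", "e")
        assert fit.params["x"] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se["x"] == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_robust_se_matches_lifelines(self, rng):
        from lifelines import CoxPHFitter

        df = _exp_cohort(rng, n=250)
        fit = cox_fit(df, "t", "e", ["x"], robust=True)
        cph = CoxPHFitter()
        cph.fit(df, "t", "e", robust=True)
        assert fit.robust_se["x"] == pytest.approx(cph.standard_errors_["x"], rel=1e-4)

    def test_rescaling_covariate_by_100(self, rng):
        df = _exp_cohort(rng, n=200)
        df["x100"] = df["x"] * 100
        a = cox_fit(df, "t", "e", ["x"])
        b = cox_fit(df, "t", "e", ["x100"])
        assert b.params["x100"] == pytest.approx(a.params["x"] / 100, rel=1e-6)
        assert b.loglik == pytest.approx(a.loglik, abs=1e-6)

    def test_constant_covariate_raises(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0], "e": [1, 1, 0], "x": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, "t", "e", ["x"])

    def test_no_events_raises(self):
        df = pd.DataFrame({"t": [1.0, 2.0], "e": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="event"):
            cox_fit(df, "t", "e", ["x"])

    def test_monotone_likelihood_flagged(self):
        # perfectly separating covariate: all events in one group first
        df = pd.DataFrame(
            {"t": np.arange(1.0, 21.0), "e": [1] * 10 + [0] * 10, "x": [1.0] * 10 + [0.0] * 10}
        )
        with pytest.raises(RuntimeError, match="monotone"):
            cox_fit(df, "t", "e", ["x"])


class TestSchoenfeld:
    def test_time_varying_effect_detected(self):
        gen = np.random.default_rng(31)
        detected = 0
        n_sims = 40
        for _ in range(n_sims):
            n = 1000
            x = gen.normal(size=n)
            # effect +1 before t0, -1 after: beta(t) crosses zero
            t0 = 0.3
            T1 = gen.exponential(1 / np.exp(1.0 * x))
            T = np.where(T1 <= t0, T1, t0 + gen.exponential(1 / np.exp(-1.0 * x)))
            df = pd.DataFrame({"t": T, "e": np.ones(n, dtype=int), "x": x})
            fit = cox_fit(df, "t", "e", ["x"])
            out = schoenfeld_test(fit, time=df["t"].to_numpy(), event=df["e"].to_numpy())
            detected += out.loc["x", "p"] < 0.05
        assert detected / n_sims > 0.8

    def test_null_not_rejected_on_average(self):
        gen = np.random.default_rng(32)
        rej = 0
        n_sims = 100
        for _ in range(n_sims):
            df = _exp_cohort(gen, n=150)
            fit = cox_fit(df, "t", "e", ["x"])
            out = schoenfeld_test(fit, time=df["t"].to_numpy(), event=df["e"].to_numpy())
            rej += out.loc["x", "p"] < 0.05
        assert rej / n_sims < 0.12

    def test_global_row_present(self, rng):
        df = _exp_cohort(rng, n=200)
        df["z"] = rng.normal(size=200)
        fit = cox_fit(df, "t", "e", ["x", "z"])
        out = schoenfeld_test(fit, time=df["t"].to_numpy(), event=df["e"].to_numpy())
        assert list(out.index) == ["x", "z", "GLOBAL"]
        assert out.loc["GLOBAL", "df"] == 2

    def test_identity_and_rank_transforms_available(self, rng):
        df = _exp_cohort(rng, n=150)
        fit = cox_fit(df, "t", "e", ["x"])
        for transform in ("identity", "rank"):
            out = schoenfeld_test(fit, transform=transform)
            assert 0 <= out.loc["x", "p"] <= 1


class TestAUCt:
    def test_uncensored_matches_empirical_auc(self, rng):
        n = 150
        marker = rng.normal(size=n)
        T = rng.exponential(1 / np.exp(0.8 * marker))
        est = auc_t(marker, T, np.ones(n, dtype=int), [np.quantile(T, 0.3), np.quantile(T, 0.6)], n_boot=0)
        for j, t in enumerate(est.times):
            cases = T <= t
            oracle = roc_auc_score(cases.astype(int), marker)
            assert est.auc[j] == pytest.approx(oracle, abs=1e-12)

    def test_time_as_marker_perfectly_anticoncordant(self, rng):
        T = rng.exponential(1, 100)
        est = auc_t(T, T, np.ones(100, dtype=int), [np.quantile(T, 0.5)], n_boot=0)
        assert est.auc[0] == pytest.approx(0.0)
        est_flip = auc_t(-T, T, np.ones(100, dtype=int), [np.quantile(T, 0.5)], n_boot=0)
        assert est_flip.auc[0] == pytest.approx(1.0)

    def test_independent_marker_near_half(self, rng):
        n = 1500
        marker = rng.normal(size=n)
        T = rng.exponential(1, n)
        C = rng.exponential(1.5, n)
        est = auc_t(marker, np.minimum(T, C), (T <= C).astype(int), [0.5, 1.0], n_boot=0)
        assert np.all(np.abs(est.auc - 0.5) < 0.05)

    def test_beyond_last_event_equals_final_status_auc(self, rng):
        n = 120
        marker = rng.normal(size=n)
        T = rng.exponential(1 / np.exp(marker))
        t_max = T.max()
        est = auc_t(marker, T, np.ones(n, dtype=int), [t_max], n_boot=0)
        # all subjects are cases except the very last survivor
        assert np.isnan(est.auc[0]) or 0 <= est.auc[0] <= 1

    def test_bootstrap_ci_brackets_point(self, rng):
        df = _exp_cohort(rng, n=200)
        est = auc_t(df["x"].to_numpy(), df["t"].to_numpy(), df["e"].to_numpy(), [0.5],
                    n_boot=100, rng=np.random.default_rng(0))
        assert est.ci_lower[0] <= est.auc[0] <= est.ci_upper[0]

    def test_agrees_with_scikit_survival_when_uncensored(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc

        n = 200
        marker = rng.normal(size=n)
        T = rng.exponential(1 / np.exp(0.5 * marker))
        y = np.array([(True, t) for t in T], dtype=[("event", "?"), ("time", "<f8")])
        grid = [np.quantile(T, 0.4)]
        theirs, _ = cumulative_dynamic_auc(y, y, marker, grid)
        est = auc_t(marker, T, np.ones(n, dtype=int), grid, n_boot=0)
        assert est.auc[0] == pytest.approx(theirs[0], abs=1e-9)


class TestAHR:
    def test_unit_weights_equal_breslow_cox(self, rng):
        df = _exp_cohort(rng, n=300)
        unit = ahr_fit(df, "t", "e", ["x"], weight_fn=lambda t: 1.0)
        cox = cox_fit(df, "t", "e", ["x"], ties="breslow")
        assert unit.params["x"] == pytest.approx(cox.params["x"], abs=1e-8)
        assert unit.loglik == pytest.approx(cox.loglik, abs=1e-8)

    def test_ph_limit_ahr_close_to_hr(self):
        gen = np.random.default_rng(41)
        diffs = []
        for _ in range(30):
            df = _exp_cohort(gen, n=500, beta=0.5)
            ahr = ahr_fit(df, "t", "e", ["x"])
            cox = cox_fit(df, "t", "e", ["x"])
            diffs.append(ahr.params["x"] - cox.params["x"])
        assert abs(np.mean(diffs)) < 0.05

    def test_crossing_hazards_ahr_between_period_hrs(self):
        gen = np.random.default_rng(42)
        n = 4000
        g = gen.integers(0, 2, n).astype(float)
        t0 = 0.4
        # group hazard ratio 3 before t0, 1/3 after
        T_early = gen.exponential(1 / np.exp(np.log(3.0) * g))
        T_late = t0 + gen.exponential(1 / np.exp(np.log(1 / 3.0) * g))
        T = np.where(T_early <= t0, T_early, T_late)
        df = pd.DataFrame({"t": T, "e": np.ones(n, dtype=int), "x": g})
        early = df.copy()
        early["e"] = (early["t"] <= t0).astype(int)
        early["t"] = early["t"].clip(upper=t0)
        beta_early = cox_fit(early, "t", "e", ["x"]).params["x"]
        late = df[df["t"] > t0].copy()
        beta_late = cox_fit(late, "t", "e", ["x"]).params["x"]
        beta_ahr = ahr_fit(df, "t", "e", ["x"]).params["x"]
        lo, hi = sorted([beta_early, beta_late])
        assert lo < beta_ahr < hi

    def test_reports_robust_se(self, rng):
        df = _exp_cohort(rng, n=200)
        fit = ahr_fit(df, "t", "e", ["x"])
        assert fit.robust_se is not None
        assert fit.robust_se["x"] > 0
        assert fit.weighted

    def test_prentice_weights_decreasing_and_bounded(self, rng):
        df = _exp_cohort(rng, n=300)
        w = prentice_weights(df["t"].to_numpy(), df["e"].to_numpy())
        times = np.quantile(df["t"], [0.1, 0.5, 0.9])
        values = [w(t) for t in times]
        assert values[0] <= 1.0 + 1e-9
        assert all(v >= 0 for v in values)
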