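"""Cox model, discrimination metrics and Kaplan-Meier estimation."""

import math

import numpy as np
import pandas as pd
import pytest

from symcox import (
    ConvergenceError,
    TransformSpec,
    auc_at_horizon,
    concordance_index,
    cox_fit,
    kaplan_meier,
    km_by_stratum,
    relative_hazard,
    wald_summary,
    wald_table,
)
from symcox.survival_models import _partial_loglik


# ---------------------------------------------------------------------------
# independent oracles (test-side implementations)
# ---------------------------------------------------------------------------

def breslow_loglik_1d(beta, x, time, event):
    """Closed-form partial log-likelihood for one covariate, no tied events."""
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
    return ll


def c_index_all_pairs(score, time, event):
    """Exhaustive pair enumeration with the documented admissibility rule."""
    num, pairs = 0.0, 0
    n = len(score)
    for i in range(n):
        if event[i] != 1:
            continue
        for j in range(n):
            if j == i:
                continue
            if time[i] < time[j] or (time[i] == time[j] and event[j] == 0):
                pairs += 1
                if score[i] > score[j]:
                    num += 1.0
                elif score[i] == score[j]:
                    num += 0.5
    return num / pairs


# ---------------------------------------------------------------------------
# cox_fit
# ---------------------------------------------------------------------------

class TestCoxFit:
    def test_toy_binary_covariate_matches_grid_search(self):
        """6-subject toy, one binary covariate, no ties: the Newton solution
        matches a 1-D brute-force grid over the closed-form likelihood."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        model = cox_fit(pd.DataFrame({"x": x}), time, event)

        grid = np.linspace(-4, 4, 80001)
        lls = [breslow_loglik_1d(b, x, time, event) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert model.coef[0] == pytest.approx(beta_grid, abs=1e-4)
        assert model.ll_model == pytest.approx(max(lls), abs=1e-8)
        assert model.ll_null == pytest.approx(
            breslow_loglik_1d(0.0, x, time, event), abs=1e-10
        )

    def test_aic_and_lr_identities(self, default_cohort):
        X = default_cohort.covariate_matrix(
            ["age", "ejection_fraction", "serum_creatinine"]
        )
        m = cox_fit(X, default_cohort.time, default_cohort.event)
        assert m.converged
        assert m.lr_statistic == pytest.approx(
            2 * (m.ll_model - m.ll_null), abs=1e-10
        )
        assert m.lr_statistic >= 0
        assert m.ll_model >= m.ll_null
        assert m.partial_aic == pytest.approx(-2 * m.ll_model + 2 * 3, abs=1e-10)

    def test_matches_lifelines(self, default_cohort):
        import lifelines

        X = default_cohort.covariate_matrix(
            ["age", "ejection_fraction", "serum_creatinine"]
        )
        m = cox_fit(X, default_cohort.time, default_cohort.event)
        df = X.copy()
        df["T"] = default_cohort.time
        df["E"] = default_cohort.event
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        # both solvers approach the same optimum; lifelines stops a little
        # earlier, so agreement is to its tolerance, not machine precision
        np.testing.assert_allclose(m.coef, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(
            m.se, cph.standard_errors_.values, atol=1e-5
        )
        assert m.ll_model == pytest.approx(cph.log_likelihood_, abs=1e-6)
        assert m.ll_model >= cph.log_likelihood_ - 1e-9

    def test_scale_equivariance(self, default_cohort):
        """Standardizing a covariate multiplies its coefficient by the scale
        and leaves ll, LR, C-index and AUC unchanged."""
        co = default_cohort
        X = co.covariate_matrix(["age", "serum_creatinine"])
        m1 = cox_fit(X, co.time, co.event)
        mscale, s = 60.0, 13.0
        X2 = X.copy()
        X2["age"] = (X2["age"] - mscale) / s
        m2 = cox_fit(X2, co.time, co.event)
        assert m2.coef[0] == pytest.approx(m1.coef[0] * s, rel=1e-8)
        assert m2.ll_model == pytest.approx(m1.ll_model, abs=1e-8)
        assert m2.lr_statistic == pytest.approx(m1.lr_statistic, abs=1e-8)
        s1 = m1.linear_predictor(X)
        s2 = m2.linear_predictor(X2)
        assert concordance_index(s1, co.time, co.event) == pytest.approx(
            concordance_index(s2, co.time, co.event), abs=1e-12
        )
        h = float(np.median(co.time))
        assert auc_at_horizon(s1, co.time, co.event, h) == pytest.approx(
            auc_at_horizon(s2, co.time, co.event, h), abs=1e-12
        )

    def test_efron_equals_breslow_without_ties(self, default_cohort):
        X = default_cohort.covariate_matrix(["age", "ejection_fraction"])
        assert len(np.unique(default_cohort.time)) == default_cohort.n
        me = cox_fit(X, default_cohort.time, default_cohort.event, ties="efron")
        mb = cox_fit(X, default_cohort.time, default_cohort.event, ties="breslow")
        np.testing.assert_allclose(me.coef, mb.coef, atol=1e-8)
        assert me.ll_model == pytest.approx(mb.ll_model, abs=1e-8)

    def test_efron_handles_tied_event_times(self):
        import lifelines

        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(20, size=n) * np.exp(-0.5 * x))  # many ties
        t = np.clip(t, 1, None)
        e = rng.binomial(1, 0.7, size=n)
        m = cox_fit(pd.DataFrame({"x": x}), t, e, ties="efron")
        df = pd.DataFrame({"x": x, "T": t, "E": e})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert m.coef[0] == pytest.approx(cph.params_.iloc[0], abs=1e-6)
        assert m.ll_model == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_score_test_equals_logrank_for_binary_covariate(self):
        """At b = 0 the Cox score statistic for a single binary covariate
        equals the log-rank chi-square (no tied event times)."""
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(7)
        n = 80
        g = rng.binomial(1, 0.5, size=n).astype(float)
        t = rng.exponential(10.0 + 10.0 * g)
        e = np.ones(n, dtype=int)
        order = np.argsort(-t, kind="stable")
        ll0, grad, info = _partial_loglik(
            np.zeros(1), g[order][:, None], t[order], e[order], "efron"
        )
        score_stat = float(grad[0] ** 2 / info[0, 0])
        res = logrank_test(t[g == 0], t[g == 1])
        assert score_stat == pytest.approx(res.test_statistic, rel=1e-6)

    def test_monotone_likelihood_flagged_not_divergent(self):
        t = np.arange(1.0, 25.0)
        x = -t  # perfectly orders the hazard: beta wants +infinity
        m = cox_fit(pd.DataFrame({"x": x}), t, np.ones_like(t, dtype=int))
        assert not m.converged
        assert m.diagnostics
        with pytest.raises(ConvergenceError):
            wald_summary(m)

    def test_preconditions(self, small_cohort):
        t, e = small_cohort.time, small_cohort.event
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"c": np.ones(small_cohort.n)}), t, e)
        with pytest.raises(ValueError, match="positive"):
            cox_fit(
                pd.DataFrame({"x": small_cohort.column("age")}),
                np.zeros(small_cohort.n),
                e,
            )
        few = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 3.0]}
        )
        with pytest.raises(ValueError, match="events"):
            cox_fit(few, np.array([1.0, 2.0, 3.0]), np.array([1, 0, 0]))


class TestWald:
    def test_hr_and_ci_consistency(self, default_cohort):
        X = default_cohort.covariate_matrix(["age", "serum_creatinine"])
        m = cox_fit(X, default_cohort.time, default_cohort.event)
        for row in wald_summary(m, confidence=0.95):
            assert row.hr == pytest.approx(math.exp(row.coef), rel=1e-12)
            assert row.hr_lower < row.hr < row.hr_upper
            assert row.z == pytest.approx(row.coef / row.se, rel=1e-12)
            # CI symmetric about the HR on the log scale
            assert math.log(row.hr_upper) - math.log(row.hr) == pytest.approx(
                math.log(row.hr) - math.log(row.hr_lower), abs=1e-10
            )

    def test_se_matches_numerical_hessian(self):
        """Wald SE from the inverse information agrees with a brute-force
        second derivative of the partial log-likelihood to 3 s.f."""
        time = np.array([3.0, 5.0, 7.0, 11.0, 13.0, 17.0, 19.0, 23.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([0.2, 1.1, -0.3, 0.8, -1.2, 0.5, 1.4, -0.7])
        m = cox_fit(pd.DataFrame({"x": x}), time, event)
        b = m.coef[0]
        h = 1e-5
        d2 = (
            breslow_loglik_1d(b + h, x, time, event)
            - 2 * breslow_loglik_1d(b, x, time, event)
            + breslow_loglik_1d(b - h, x, time, event)
        ) / h**2
        se_numeric = math.sqrt(-1.0 / d2)
        assert m.se[0] == pytest.approx(se_numeric, rel=1e-3)

    def test_table_column_order(self, default_cohort):
        X = default_cohort.covariate_matrix(["age"])
        m = cox_fit(X, default_cohort.time, default_cohort.event)
        tbl = wald_table(m)
        assert list(tbl.columns) == [
            "coef", "HR", "HR lower 95%", "HR upper 95%", "z", "p",
        ]


@pytest.fixture(scope="module")
def model(default_cohort):
    X = default_cohort.covariate_matrix(["serum_creatinine"])
    return cox_fit(X, default_cohort.time, default_cohort.event)


class TestRelativeHazard:
    def test_untransformed_origin_independent(self, model):
        r1 = relative_hazard(model, "serum_creatinine", 1.0, 0.1)
        r2 = relative_hazard(model, "serum_creatinine", 5.0, 0.1)
        assert r1 == pytest.approx(r2, rel=1e-12)
        b = model.coef[0]
        assert r1 == pytest.approx(math.exp(b * 0.1), rel=1e-12)

    def test_zero_delta_is_one(self, model):
        assert relative_hazard(model, "serum_creatinine", 2.0, 0.0) == 1.0

    def test_inverse_transform_origin_dependent(self, model):
        """With f = 1/x and b = 1 the same +5 change matters more at low
        values: hand arithmetic for 20->25 vs 60->65."""
        inv = TransformSpec.pure("inverse")
        b = model.coef[0]
        low = relative_hazard(model, "serum_creatinine", 20.0, 5.0, inv)
        high = relative_hazard(model, "serum_creatinine", 60.0, 5.0, inv)
        assert low == pytest.approx(math.exp(b * (1 / 25 - 1 / 20)), rel=1e-12)
        assert high == pytest.approx(math.exp(b * (1 / 65 - 1 / 60)), rel=1e-12)
        assert abs(math.log(low)) > abs(math.log(high))

    def test_errors(self, model):
        with pytest.raises(KeyError):
            relative_hazard(model, "age", 1.0, 0.1)
        from symcox import DomainError

        with pytest.raises(DomainError):
            relative_hazard(
                model, "serum_creatinine", -1.0, 0.5,
                TransformSpec.pure("log"),
            )


class TestConcordance:
    def test_anti_ordered_no_censoring_is_one(self):
        t = np.array([5.0, 3.0, 9.0, 1.0, 7.0])
        score = -t  # higher risk -> earlier death
        assert concordance_index(score, t, np.ones(5, int)) == 1.0

    def test_constant_score_is_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert concordance_index(np.zeros(4), t, np.ones(4, int)) == 0.5

    def test_matches_all_pairs_enumeration_with_censoring(self, rng):
        for trial in range(5):
            n = 20
            t = np.round(rng.exponential(10, n), 1) + 0.5
            e = rng.binomial(1, 0.6, n)
            score = np.round(rng.normal(size=n), 1)  # induces score ties
            assert concordance_index(score, t, e) == pytest.approx(
                c_index_all_pairs(score, t, e), abs=1e-12
            )

    def test_negation_identity_without_ties(self, rng):
        n = 30
        t = rng.exponential(10, n)
        e = rng.binomial(1, 0.7, n)
        score = rng.normal(size=n)
        c = concordance_index(score, t, e)
        assert concordance_index(-score, t, e) == pytest.approx(1 - c, abs=1e-12)

    def test_no_comparable_pairs_error(self):
        with pytest.raises(ValueError, match="comparable"):
            concordance_index([1.0, 2.0], [3.0, 4.0], [0, 0])


class TestHorizonAuc:
    def test_perfect_separation(self):
        t = np.array([10.0, 20.0, 300.0, 310.0])
        e = np.array([1, 1, 0, 0])
        score = np.array([5.0, 4.0, 1.0, 0.5])
        assert auc_at_horizon(score, t, e, 285.0) == 1.0

    def test_no_early_censoring_equals_rank_auc(self, rng):
        """Without censoring before the horizon the estimator reduces to the
        plain two-sample rank AUC (all-pairs counting oracle)."""
        n = 40
        t = rng.exponential(100, n) + 1
        e = np.ones(n, int)
        score = rng.normal(size=n)
        h = 80.0
        cases = score[t <= h]
        controls = score[t > h]
        gt = sum((c > o) for c in cases for o in controls)
        eq = sum((c == o) for c in cases for o in controls)
        oracle = (gt + 0.5 * eq) / (len(cases) * len(controls))
        assert auc_at_horizon(score, t, e, h) == pytest.approx(oracle, abs=1e-12)

    def test_include_variant_is_rank_auc_of_death_label(self, default_cohort):
        co = default_cohort
        score = co.column("serum_creatinine")
        h = float(np.max(co.time))
        auc = auc_at_horizon(score, co.time, co.event, h,
                             censored_controls="include")
        cases = score[co.event == 1]
        controls = score[co.event == 0]
        gt = (cases[:, None] > controls[None, :]).mean()
        eq = (cases[:, None] == controls[None, :]).mean()
        assert auc == pytest.approx(gt + 0.5 * eq, abs=1e-12)

    def test_ipcw_equals_plain_when_uncensored(self, rng):
        n = 60
        t = rng.exponential(50, n) + 1
        e = np.ones(n, int)
        score = rng.normal(size=n)
        h = float(np.median(t))
        plain = auc_at_horizon(score, t, e, h)
        ipcw = auc_at_horizon(score, t, e, h, censored_controls="ipcw")
        assert ipcw == pytest.approx(plain, abs=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError, match="case"):
            auc_at_horizon([1.0, 2.0], [10.0, 20.0], [0, 0], 15.0)
        with pytest.raises(ValueError):
            auc_at_horizon([1.0, 2.0], [10.0, 20.0], [1, 1], -5.0)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        t = np.array([2.0, 4.0, 4.0, 6.0, 9.0])
        km = kaplan_meier(t, np.ones(5, int))
        for tt, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(t > tt), abs=1e-12)

    def test_textbook_worked_example(self):
        """times {6, 6, 6, 7+, 10, 13+}: hand product-limit calculation."""
        t = np.array([6.0, 6.0, 6.0, 7.0, 10.0, 13.0])
        e = np.array([1, 1, 1, 0, 1, 0])
        km = kaplan_meier(t, e)
        np.testing.assert_array_equal(km.times, [6.0, 10.0])
        # S(6) = 1 - 3/6; S(10) = (1/2)(1 - 1/2)
        np.testing.assert_allclose(km.survival, [0.5, 0.25], atol=1e-12)
        np.testing.assert_array_equal(km.n_at_risk, [6, 2])
        np.testing.assert_array_equal(km.n_events, [3, 1])
        # Greenwood: S^2 * sum d/(n(n-d))
        v6 = 0.5**2 * (3 / (6 * 3))
        v10 = 0.25**2 * (3 / (6 * 3) + 1 / (2 * 1))
        np.testing.assert_allclose(km.variance, [v6, v10], atol=1e-12)

    def test_censored_at_event_time_stays_at_risk(self):
        km = kaplan_meier([5.0, 5.0], [1, 0])
        assert km.n_at_risk[0] == 2
        assert km.survival[0] == pytest.approx(0.5)

    def test_monotone_with_s0_one_and_bands_bracket(self, default_cohort):
        km = kaplan_meier(default_cohort.time, default_cohort.event)
        assert km.survival_at(0.0) == 1.0
        assert (np.diff(km.survival) <= 1e-15).all()
        assert ((km.survival >= 0) & (km.survival <= 1)).all()
        inner = (km.survival > 0) & (km.survival < 1)
        assert (km.ci_lower[inner] <= km.survival[inner]).all()
        assert (km.ci_upper[inner] >= km.survival[inner]).all()

    def test_matches_lifelines_with_bands(self, default_cohort):
        import lifelines

        co = default_cohort
        km = kaplan_meier(co.time, co.event)
        kmf = lifelines.KaplanMeierFitter().fit(co.time, co.event)
        np.testing.assert_allclose(
            km.survival,
            kmf.survival_function_.loc[km.times, "KM_estimate"].values,
            atol=1e-12,
        )
        ci = kmf.confidence_interval_.loc[km.times].values
        np.testing.assert_allclose(
            np.c_[km.ci_lower, km.ci_upper], ci, atol=1e-12
        )

    def test_survival_at_step_lookup(self):
        km = kaplan_meier([2.0, 4.0, 8.0], [1, 1, 1])
        assert km.survival_at(1.9) == 1.0
        assert km.survival_at(2.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.0, before=True) == 1.0
        assert km.survival_at(100.0) == 0.0


class TestKmByStratum:
    def test_single_bin_equals_full_curve(self, default_cohort):
        co = default_cohort
        ef = co.column("ejection_fraction")
        curves = km_by_stratum(
            co, "ejection_fraction", [ef.min() - 1, ef.max()]
        )
        assert len(curves) == 1
        (curve,) = curves.values()
        full = kaplan_meier(co.time, co.event)
        np.testing.assert_allclose(curve.survival, full.survival, atol=1e-15)

    def test_strong_ef_effect_orders_curves(self):
        from symcox import SimulationConfig, generate_cohort

        cfg = SimulationConfig(
            n=3000, seed=55,
            true_transforms={
                "ejection_fraction": TransformSpec.pure("inverse")
            },
            true_betas={"ejection_fraction": 80.0},
            baseline_rate=5e-4,
        )
        co = generate_cohort(cfg)
        curves = km_by_stratum(co, "ejection_fraction", [13.0, 25.0, 81.0])
        low, high = curves["(13, 25]"], curves["(25, 81]"]
        t_half = float(np.median(co.time))
        assert low.survival_at(t_half) < high.survival_at(t_half)

    def test_empty_stratum_omitted_with_warning(self, default_cohort, caplog):
        co = default_cohort
        ef = co.column("ejection_fraction")
        hi = float(ef.max())
        with caplog.at_level("WARNING", logger="symcox.survival_models"):
            curves = km_by_stratum(
                co, "ejection_fraction", [ef.min() - 1, hi, hi + 5, hi + 10]
            )
        assert len(curves) == 1
        assert "empty" in caplog.text

    def test_non_covering_bins_error(self, default_cohort):
        with pytest.raises(ValueError, match="cover"):
            km_by_stratum(default_cohort, "ejection_fraction", [30.0, 40.0])
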