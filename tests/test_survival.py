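"""Cox model, Kaplan-Meier, log-rank and the bivariate hazard table."""

import numpy as np
import pandas as pd
import pytest

from immunotopo.survival import (
    REFERENCE_PHENOTYPE,
    all_phenotypes,
    build_design,
    cox_score_test,
    density_cox,
    fit_cox,
    fit_phenotype_cox,
    km_by_group,
    km_estimate,
    logrank_test,
    phenotype_hazard_table,
    phenotype_name,
    _efron_loglik,
)
from immunotopo.synthetic import SurvivalSpec, simulate_cohort


def grid_search_beta(x, time, event, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force maximizer of the (untied) Cox partial likelihood."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    betas = np.arange(lo, hi + step, step)
    best_beta, best_ll = None, -np.inf
    order = np.argsort(time)
    x, time, event = x[order], time[order], event[order]
    for b in betas:
        eta = b * x
        ll = 0.0
        for i in range(len(time)):
            if event[i]:
                risk = eta[i:]  # everyone with time >= t_i (sorted, no ties)
                ll += eta[i] - np.log(np.exp(risk).sum())
        if ll > best_ll:
            best_ll, best_beta = ll, b
    return best_beta


class TestCox:
    def test_two_group_beta_matches_grid_search_oracle(self):
        """4 patients, no ties: Newton beta equals the grid maximizer."""
        time = np.array([1.0, 3.0, 2.0, 4.0])
        event = np.array([True, True, True, True])
        x = np.array([0.0, 0.0, 1.0, 1.0])
        res = fit_cox(pd.DataFrame({"g": x}), time, event)
        oracle = grid_search_beta(x, time, event)
        assert res.table.loc["g", "coef"] == pytest.approx(oracle, abs=1e-3)

    def test_gradient_norm_and_information_at_optimum(self):
        rng = np.random.default_rng(0)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        time = rng.exponential(np.exp(-0.7 * x))
        event = np.ones(n, bool)
        res = fit_cox(pd.DataFrame({"g": x}), time, event)
        assert res.grad_norm < 1e-8
        eigvals = np.linalg.eigvalsh(res.information)
        assert (eigvals > 0).all()  # concave partial likelihood at beta-hat

    def test_matches_lifelines_on_simulated_cohort(self):
        lifelines = pytest.importorskip("lifelines")
        probs = {ph: 1 / 9 for ph in all_phenotypes()}
        spec = SurvivalSpec(log_hr={phenotype_name("excluded", "hot"): 0.8})
        co = simulate_cohort(600, probs, survival=spec, seed=12)
        X = build_design(co.patients)
        res = fit_cox(X, co.patients["time"], co.patients["event"])
        df = pd.concat(
            [co.patients[["time"]], co.patients["event"].astype(int), X], axis=1
        )
        cph = lifelines.CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(
            res.table["coef"].to_numpy(),
            cph.params_.reindex(res.table.index).to_numpy(),
            atol=1e-5,
        )

    def test_null_covariate_ci_covers_zero(self):
        """Balanced binary covariate with no effect: 95% CI covers 0
        in at least 93 of 100 simulated datasets."""
        rng = np.random.default_rng(42)
        covered = 0
        for _ in range(100):
            n = 80
            x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            time = rng.exponential(1.0, n)
            event = np.ones(n, bool)
            res = fit_cox(pd.DataFrame({"g": x}), time, event)
            lo, hi = res.table.loc["g", ["ci_low", "ci_high"]]
            covered += lo <= 1.0 <= hi  # HR scale
        assert covered >= 93

    def test_requires_events_and_variation(self):
        with pytest.raises(ValueError):
            fit_cox(pd.DataFrame({"g": [0.0, 1.0]}), [1.0, 2.0], [True, False])
        with pytest.raises(ValueError):
            fit_cox(pd.DataFrame({"g": [1.0, 1.0, 1.0]}), [1, 2, 3], [True, True, True])

    def test_complete_separation_is_flagged_not_fitted(self):
        """A group with no events is non-estimable, not an infinite HR."""
        x = np.r_[np.zeros(20), np.ones(10)]
        time = np.r_[np.linspace(1, 3, 20), np.full(10, 5.0)]
        event = np.r_[np.ones(20, bool), np.zeros(10, bool)]
        other = np.tile([0.0, 1.0], 15)
        res = fit_cox(pd.DataFrame({"sep": x, "ok": other}), time, event)
        assert "sep" in res.non_estimable
        assert np.isnan(res.table.loc["sep", "coef"])
        assert np.isfinite(res.table.loc["ok", "coef"])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = km_estimate([1.0, 2.0, 3.0, 4.0], [True] * 4)
        np.testing.assert_allclose(km["survival"], [1.0, 0.75, 0.5, 0.25, 0.0])
        rng = np.random.default_rng(1)
        t = rng.exponential(1.0, 57)
        km = km_estimate(t, np.ones(57, bool))
        for _, row in km.iloc[1:].iterrows():
            assert row["survival"] == pytest.approx((t > row["time"]).mean(), abs=1e-12)

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [False] * 3)
        assert (km["survival"] == 1.0).all()

    def test_six_patient_worked_example_with_censoring(self):
        """Hand-computed product over risk sets:
        times 1,2+,3,4,5+,6 -> S = 5/6, 5/8, 5/12, 0."""
        time = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        event = [True, False, True, True, False, True]
        km = km_estimate(time, event)
        np.testing.assert_allclose(km["survival"], [1.0, 5 / 6, 5 / 8, 5 / 12, 0.0])
        # Greenwood at t=3: S^2 * (1/(6*5) + 1/(4*3))
        var_t3 = (5 / 8) ** 2 * (1 / 30 + 1 / 12)
        assert km.loc[km["time"] == 3.0, "var"].iloc[0] == pytest.approx(var_t3)

    def test_matches_lifelines_with_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2)
        t = rng.exponential(1.0, 100)
        c = rng.exponential(1.5, 100)
        time, event = np.minimum(t, c), t <= c
        km = km_estimate(time, event)
        kmf = lifelines.KaplanMeierFitter().fit(time, event)
        ours = km.set_index("time")["survival"]
        theirs = kmf.survival_function_["KM_estimate"]
        np.testing.assert_allclose(ours, theirs.loc[ours.index], atol=1e-12)

    def test_km_by_group_long_format(self):
        df = pd.DataFrame(
            {"phenotype": ["a"] * 3 + ["b"] * 3, "time": [1, 2, 3, 1, 2, 3],
             "event": [True] * 6}
        )
        out = km_by_group(df)
        assert set(out.columns) == {"group", "time", "survival", "ci_low", "ci_high", "n_risk"}
        assert set(out["group"]) == {"a", "b"}


def logrank_tabulation_oracle(times, events, groups):
    """Independent 2x2-per-event-time tabulation for two groups."""
    times, events, groups = map(np.asarray, (times, events, groups))
    O = E = V = 0.0
    for t in np.unique(times[events.astype(bool)]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & events.astype(bool)).sum()
        d1 = ((times == t) & events.astype(bool) & (groups == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, bool)
        res = logrank_test([(t, e), (t.copy(), e.copy())])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_tabulation_oracle_on_ten_patients(self):
        times = [1, 2, 2, 3, 4, 5, 6, 7, 8, 9.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 1, 0]
        groups = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
        times, events, groups = map(np.asarray, (times, events, groups))
        res = logrank_test(
            [(times[groups == 0], events[groups == 0].astype(bool)),
             (times[groups == 1], events[groups == 1].astype(bool))]
        )
        oracle = logrank_tabulation_oracle(times, events, groups)
        assert res.statistic == pytest.approx(oracle, rel=1e-9)

    def test_equals_cox_score_test_on_untied_data(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1.0, 150)
        e = rng.random(150) < 0.8
        g = rng.integers(0, 2, 150)
        res = logrank_test([(t[g == 0], e[g == 0]), (t[g == 1], e[g == 1])])
        chi2, df, _ = cox_score_test(pd.DataFrame({"g": g.astype(float)}), t, e)
        assert df == 1
        assert res.statistic == pytest.approx(chi2, abs=1e-6)

    def test_power_under_threefold_hazard(self):
        """HR = 3 with 200 per group: rejects at 5% in >= 95/100 replicates."""
        rng = np.random.default_rng(4)
        rejections = 0
        for _ in range(100):
            t0 = rng.exponential(1.0, 200)
            t1 = rng.exponential(1.0 / 3.0, 200)
            e = np.ones(200, bool)
            res = logrank_test([(t0, e), (t1, e.copy())])
            rejections += res.p < 0.05
        assert rejections >= 95

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([(np.array([1.0]), np.array([True]))])


class TestPhenotypeHazardTable:
    def test_reference_only_cohort(self):
        rng = np.random.default_rng(5)
        n = 40
        records = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "time": rng.exponential(10, n),
                "event": np.ones(n, bool),
                "stage": rng.choice(["I", "II", "III", "IV"], n),
                "age": rng.normal(65, 8, n),
                "sex": rng.choice(["male", "female"], n),
                "phenotype": REFERENCE_PHENOTYPE,
            }
        )
        tab = phenotype_hazard_table(records)
        assert tab["hr"].loc["cold", "cold"] == 1.0
        assert tab["n"].loc["cold", "cold"] == n
        assert tab["hr"].drop(index="cold").isna().all().all()
        assert (tab["n"].to_numpy().sum()) == n

    def test_recovers_planted_hazard_ratio(self):
        """True HR 2.0 for one phenotype at n=2000: estimate in [1.7, 2.4]."""
        target = phenotype_name("excluded", "hot")
        probs = {ph: 1 / 9 for ph in all_phenotypes()}
        spec = SurvivalSpec(log_hr={target: np.log(2.0)})
        co = simulate_cohort(2000, probs, survival=spec, seed=6)
        tab = phenotype_hazard_table(co.patients)
        assert 1.7 <= tab["hr"].loc["excluded", "hot"] <= 2.4

    def test_empty_cells_never_receive_an_hr(self):
        probs = {REFERENCE_PHENOTYPE: 0.5, phenotype_name("hot", "hot"): 0.5}
        co = simulate_cohort(300, probs, seed=7)
        tab = phenotype_hazard_table(co.patients)
        empty = tab["n"] == 0
        assert empty.to_numpy().sum() == 7
        assert tab["hr"].where(empty).isna().all().all()

    def test_missing_phenotypes_are_dropped(self):
        probs = {ph: 1 / 9 for ph in all_phenotypes()}
        co = simulate_cohort(300, probs, seed=8)
        patients = co.patients.copy()
        patients.loc[:20, "phenotype"] = None
        res = fit_phenotype_cox(patients)
        assert res.n == len(patients) - 21


def test_density_cox_null_effect_near_one():
    """Continuous density covariate with no true effect: HR close to 1."""
    probs = {ph: 1 / 9 for ph in all_phenotypes()}
    co = simulate_cohort(800, probs, seed=9)
    rng = np.random.default_rng(10)
    records = co.patients.assign(core_density=rng.exponential(100, len(co.patients)))
    res = density_cox(records, "core_density")
    lo, hi = res.table.loc["core_density", ["ci_low", "ci_high"]]
    assert lo <= 1.0 <= hi


def test_efron_reduces_to_breslow_without_ties():
    rng = np.random.default_rng(11)
    n = 50
    x = rng.normal(0, 1, (n, 2))
    t = rng.exponential(1, n)
    e = rng.random(n) < 0.7
    beta = np.array([0.3, -0.2])
    ll, grad, info = _efron_loglik(beta, x, t, e)
    # Breslow computed directly (valid without ties)
    order = np.argsort(t)
    xs, ts, es = x[order] - x.mean(0), t[order], e[order]
    eta = xs @ beta
    ll_b = 0.0
    for i in range(n):
        if es[i]:
            ll_b += eta[i] - np.log(np.exp(eta[i:]).sum())
    assert ll == pytest.approx(ll_b, rel=1e-10)
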