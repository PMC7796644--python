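import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize_scalar

from wcetrial.cox import (ConvergenceError, SingularDesignError, aic, deviance,
                          delta_method_band, fit_cox_tv, fit_wce,
                          grambsch_global_test, hr_for_dose_pattern,
                          schoenfeld_residuals, select_window, WeightEstimate)
from wcetrial.exposure import (DoseHistory, make_spline_basis,
                               wce_artificial_covariates, WeightFunction)


def explicit_partial_loglik(beta, table):
    """Naive risk-set evaluation of the (no-ties) partial likelihood."""
    ll = 0.0
    ev = table[table.event]
    for row in ev.itertuples():
        at_risk = table[(table.start < row.stop) & (table.stop >= row.stop)]
        eta = beta * at_risk["x"].to_numpy()
        ll += beta * row.x - np.log(np.exp(eta).sum())
    return ll


class TestPartialLikelihoodEngine:
    def test_four_subject_closed_form(self, four_subject_table):
        fit = fit_cox_tv(four_subject_table, ["x"])
        assert fit.params["x"] == pytest.approx(0.5 * np.log(2), abs=1e-8)
        assert fit.score_norm < 1e-6

    def test_matches_grid_search_oracle(self, four_subject_table):
        res = minimize_scalar(
            lambda b: -explicit_partial_loglik(b, four_subject_table),
            bounds=(-3, 3), method="bounded",
            options={"xatol": 1e-10})
        fit = fit_cox_tv(four_subject_table, ["x"])
        assert fit.params["x"] == pytest.approx(res.x, abs=1e-4)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_random_small_tables_match_oracle(self):
        # oracle equivalence on tiny datasets with one covariate
        rng = np.random.default_rng(11)
        for _ in range(5):
            n = rng.integers(3, 7)
            tab = pd.DataFrame({
                "patient_id": np.arange(n), "start": 0.0,
                "stop": rng.uniform(0.5, 5, n).round(2),
                "event": rng.random(n) < 0.7,
                "x": rng.normal(size=n).round(2)})
            if tab.event.sum() == 0 or tab["x"].nunique() == 1:
                continue
            try:
                fit = fit_cox_tv(tab, ["x"])
            except ConvergenceError:
                continue   # monotone likelihood on tiny data
            res = minimize_scalar(lambda b: -explicit_partial_loglik(b, tab),
                                  bounds=(-10, 10), method="bounded",
                                  options={"xatol": 1e-10})
            if abs(res.x) > 9:
                continue   # maximiser at the bound: monotone likelihood
            assert fit.params["x"] == pytest.approx(res.x, abs=1e-4)

    def test_duplicated_data_invariance(self, four_subject_table):
        fit1 = fit_cox_tv(four_subject_table, ["x"], ties="breslow")
        dup = pd.concat([four_subject_table,
                         four_subject_table.assign(patient_id=[5, 6, 7, 8])],
                        ignore_index=True)
        fit2 = fit_cox_tv(dup, ["x"], ties="breslow")
        assert fit2.params["x"] == pytest.approx(fit1.params["x"], abs=1e-8)
        assert fit1.cov.iloc[0, 0] == pytest.approx(2 * fit2.cov.iloc[0, 0], rel=1e-6)

    def test_constant_covariate_singular(self, four_subject_table):
        tab = four_subject_table.assign(z=0.0)
        with pytest.raises(SingularDesignError):
            fit_cox_tv(tab, ["z"])

    def test_matches_lifelines(self, survival_frame):
        lifelines = pytest.importorskip("lifelines")
        fit = fit_cox_tv(survival_frame, ["x1", "x2"])
        cp = lifelines.CoxPHFitter()
        cp.fit(survival_frame[["stop", "event", "x1", "x2"]],
               duration_col="stop", event_col="event")
        np.testing.assert_allclose(fit.params.to_numpy(), cp.params_.to_numpy(),
                                   atol=2e-5)
        assert fit.loglik == pytest.approx(cp.log_likelihood_, abs=1e-5)

    def test_aic_deviance_identities(self, survival_frame):
        fit = fit_cox_tv(survival_frame, ["x1", "x2"])
        assert aic(fit) == pytest.approx(deviance(fit) + 2 * fit.k)
        reduced = fit_cox_tv(survival_frame, ["x1"])
        assert (aic(fit) - aic(reduced)) == pytest.approx(
            2 * (fit.k - reduced.k) - 2 * (fit.loglik - reduced.loglik))
        # deviance difference is the likelihood-ratio statistic
        lr = 2 * (fit.loglik - reduced.loglik)
        assert deviance(reduced) - deviance(fit) == pytest.approx(lr)

    def test_covariance_symmetric_psd(self, survival_frame):
        fit = fit_cox_tv(survival_frame, ["x1", "x2"])
        cov = fit.cov.to_numpy()
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestWCEFit:
    def test_constant_basis_equals_windowed_ce(self, survival_frame):
        # a single flat basis function makes the artificial covariate a
        # windowed cumulative dose, so both routes must agree exactly
        rng = np.random.default_rng(2)
        hists = {int(i): DoseHistory(np.sort(rng.uniform(0, 10, 4)),
                                     np.ones(4))
                 for i in survival_frame.patient_id}
        basis = make_spline_basis(1000.0, 1)   # window beyond all lags
        tab = survival_frame.copy()
        from wcetrial.cox import add_wce_columns
        names = add_wce_columns(tab, hists, basis)
        # partition of unity: sum of D columns = windowed CE
        wce_sum = tab[names].sum(axis=1).to_numpy()
        ce = np.array([
            float((hists[int(r.patient_id)].times < r.stop).sum())
            for r in tab.itertuples()])
        np.testing.assert_allclose(wce_sum, ce, atol=1e-9)

    def test_weight_recovery_from_simulation(self):
        # estimated weight function correlates with the decaying truth
        from wcetrial.simulate import SimConfig, TrueModel, simulate_cohort
        from wcetrial.trial_data import build_counting_process, shift_baseline
        corr = []
        w_true = lambda u: -1.1 * 0.5 ** (np.asarray(u) / 20.0)
        for seed in range(3):
            c = simulate_cohort(SimConfig(n_patients=300),
                                TrueModel(exposure_kind="wce",
                                          weight_function=w_true, window=120.0),
                                seed=100 + seed)
            ch = shift_baseline(c.patients, c.doses, c.updates, c.outcomes)
            table = build_counting_process(ch)
            hist = DoseHistory.from_frame(ch.doses)
            fit, west = fit_wce(table, hist, 120.0, n_interior_knots=1,
                                adjust_covariates=["arm_maintenance"])
            u = np.linspace(0, 120, 60)
            corr.append(np.corrcoef(west.weight(u), w_true(u))[0, 1])
        assert sum(c > 0.9 for c in corr) >= 2

    def test_select_window_tie_prefers_smaller(self, monkeypatch):
        import wcetrial.cox as cox_mod

        class FakeFit:
            def __init__(self, a):
                self.aic = a

        def fake_fit_wce(table, histories, window, **kw):
            return FakeFit(100.0), None

        monkeypatch.setattr(cox_mod, "fit_wce", fake_fit_wce)
        sel = cox_mod.select_window(pd.DataFrame(), {}, (365.0, 120.0))
        assert sel.best_window == 120.0

    def test_select_window_requires_two_candidates(self):
        with pytest.raises(ValueError):
            select_window(pd.DataFrame(), {}, (120.0,))


class TestHRPatterns:
    @pytest.mark.parametrize("conc, reduction", [(8.0, 88), (13.0, 97), (1.0, 23)])
    def test_tbc_worked_examples(self, conc, reduction):
        # unit hazard ratio 0.77 per mg/kg at steady concentrations
        loghr = np.log(0.77)
        hr = np.exp(loghr * conc)
        assert round(100 * (1 - hr)) == reduction

    def test_tbc_pattern_curve(self):
        # single 5 mg/kg dose at day 0: concentration halves every 20 days
        p = hr_for_dose_pattern(np.log(0.77), [(0.0, 5.0)], [20.0], half_life=20.0)
        assert p.hr[0] == pytest.approx(0.77 ** 2.5)

    def test_zero_weight_function_unit_hr(self):
        basis = make_spline_basis(120, 1)
        w = WeightFunction(np.zeros(basis.n_basis), basis)
        p = hr_for_dose_pattern(w, [(0, 1), (14, 1), (28, 1)], np.linspace(1, 200, 20))
        np.testing.assert_allclose(p.hr, 1.0)

    def test_hr_one_beyond_window(self):
        basis = make_spline_basis(120, 1)
        w = WeightFunction(np.ones(basis.n_basis), basis)
        p = hr_for_dose_pattern(w, [(0.0, 2.0)], [60.0, 121.0])
        assert p.hr[0] != 1.0 and p.hr[1] == pytest.approx(1.0)


class TestDeltaMethodBand:
    def test_zero_covariance_collapses(self):
        basis = make_spline_basis(120, 1)
        west = WeightEstimate(WeightFunction(np.ones(basis.n_basis), basis),
                              np.zeros((basis.n_basis, basis.n_basis)), 120.0)
        band = delta_method_band(west, np.linspace(0, 120, 30))
        np.testing.assert_allclose(band["lo"], band["w"])
        np.testing.assert_allclose(band["hi"], band["w"])

    def test_single_basis_function_band(self):
        # 1-D delta method: band = w(u) +- 1.96 * sigma * B1(u)
        basis = make_spline_basis(120, 1)
        J = basis.n_basis
        cov = np.zeros((J, J))
        cov[0, 0] = 0.25
        theta = np.zeros(J)
        theta[0] = 1.0
        west = WeightEstimate(WeightFunction(theta, basis), cov, 120.0)
        u = np.linspace(0, 120, 50)
        band = delta_method_band(west, u)
        b1 = basis.evaluate(u)[:, 0]
        np.testing.assert_allclose(band["hi"] - band["w"], 1.96 * 0.5 * b1,
                                   atol=1e-12)

    def test_band_contains_estimate(self, survival_frame):
        rng = np.random.default_rng(4)
        hists = {int(i): DoseHistory(np.sort(rng.uniform(0, 8, 5)), np.ones(5))
                 for i in survival_frame.patient_id}
        fit, west = fit_wce(survival_frame, hists, 10.0, n_interior_knots=1)
        band = delta_method_band(west, np.linspace(0, 10, 25))
        assert (band["lo"] <= band["w"] + 1e-12).all()
        assert (band["hi"] >= band["w"] - 1e-12).all()
        assert (band["hi"] - band["lo"]).iloc[1:-1].gt(0).all()


def naive_grambsch_global(table, fit, transform):
    """Independent textbook-formula implementation with explicit loops."""
    table = table.sort_values("stop")
    ev = table[table.event]
    p = fit.k
    resid, times = [], []
    beta = fit.params.to_numpy()
    X_cols = list(fit.params.index)
    for row in ev.itertuples():
        at_risk = table[(table.start < row.stop) & (table.stop >= row.stop)]
        w = np.exp(at_risk[X_cols].to_numpy() @ beta)
        xbar = (w[:, None] * at_risk[X_cols].to_numpy()).sum(0) / w.sum()
        resid.append(np.array([getattr(row, c) for c in X_cols]) - xbar)
        times.append(row.stop)
    resid = np.asarray(resid)
    times = np.asarray(times)
    d = len(times)
    if transform == "identity":
        g = times
    elif transform == "rank":
        g = stats.rankdata(times)
    else:
        raise NotImplementedError
    gc = g - g.mean()
    U = gc @ resid
    inv_info = fit.cov.to_numpy()
    return float(d * U @ inv_info @ U / (gc @ gc))


class TestGrambschTest:
    @pytest.mark.parametrize("transform", ["identity", "rank"])
    def test_matches_independent_formula(self, survival_frame, transform):
        fit = fit_cox_tv(survival_frame, ["x1", "x2"])
        mine = grambsch_global_test(fit, survival_frame, transform=transform)
        oracle = naive_grambsch_global(survival_frame, fit, transform)
        assert mine.statistic == pytest.approx(oracle, abs=1e-6)
        assert mine.df == 2
        assert 0 <= mine.p_value <= 1

    def test_fixed_fixture_value(self, four_subject_table):
        fit = fit_cox_tv(four_subject_table, ["x"])
        res = grambsch_global_test(fit, four_subject_table, transform="identity")
        oracle = naive_grambsch_global(four_subject_table, fit, "identity")
        assert res.statistic == pytest.approx(oracle, abs=1e-10)

    def test_df_equals_k(self, survival_frame):
        fit = fit_cox_tv(survival_frame, ["x1", "x2"])
        res = grambsch_global_test(fit, survival_frame)
        assert res.df == fit.k
        assert len(res.per_covariate) == fit.k

    def test_schoenfeld_residuals_sum_near_zero(self, survival_frame):
        fit = fit_cox_tv(survival_frame, ["x1", "x2"])
        _, resid = schoenfeld_residuals(fit, survival_frame)
        np.testing.assert_allclose(resid.sum(axis=0), 0.0, atol=1e-5)
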