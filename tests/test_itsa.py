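"""Segmented-regression design, fitting, diagnostics and the policy panel."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from conftest import bartlett_hac_se, normal_equations_ols
from policypulse.itsa import (
    ITSADesign,
    PolicyEvent,
    build_design,
    counterfactual,
    default_hac_lag,
    durbin_watson,
    fit_itsa,
    newey_west_se,
    run_policy_panel,
)
from policypulse.scoring import DailyAttitudeSeries
from policypulse.synthetic import ITSGenConfig, gen_its_series


def make_series(values, start="2021-06-01"):
    values = np.asarray(values, dtype=float)
    return DailyAttitudeSeries(
        dates=pd.date_range(start, periods=len(values), freq="D"),
        values=values,
        n_comments=np.ones(len(values), dtype=int),
    )


def event_at(series, index):
    return PolicyEvent(date=series.dates[index].date())


class TestDesign:
    def test_level_and_trend_construction(self):
        series = make_series(np.linspace(0, 1, 10))
        design = build_design(series, event_at(series, 5))
        assert design.X["level"].tolist() == [0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
        assert design.X["trend"].tolist() == [0, 0, 0, 0, 0, 0, 1, 2, 3, 4]
        assert design.X["time"].tolist() == list(range(10))
        assert design.n_pre == 5 and design.n_post == 5

    @pytest.mark.parametrize("k,ncols", [(0, 4), (1, 6), (2, 8)])
    def test_fourier_column_count(self, k, ncols):
        series = make_series(np.linspace(0, 1, 30))
        design = build_design(series, event_at(series, 15), fourier_k=k)
        assert design.X.shape[1] == ncols

    def test_event_outside_window_rejected(self):
        series = make_series(np.linspace(0, 1, 10))
        with pytest.raises(ValueError, match="outside"):
            build_design(series, PolicyEvent(date=date(2022, 1, 1)))

    def test_event_on_first_day_rejected(self):
        series = make_series(np.linspace(0, 1, 10))
        with pytest.raises(ValueError):
            build_design(series, event_at(series, 0))

    def test_too_short_series_rejected(self):
        series = make_series(np.linspace(0, 1, 5))
        with pytest.raises(ValueError, match="observations"):
            build_design(series, event_at(series, 2))


class TestFit:
    def test_noiseless_exact_recovery(self):
        cfg = ITSGenConfig(beta0=0.5, beta1=0.001, beta2=0.15, beta3=-0.005, sigma=0.0)
        series, truth = gen_its_series(cfg)
        design = build_design(series, PolicyEvent(date=truth.event_date))
        fit = fit_itsa(design, series.values)
        assert fit.beta0 == pytest.approx(0.5, abs=1e-10)
        assert fit.beta1 == pytest.approx(0.001, abs=1e-12)
        assert fit.beta2 == pytest.approx(0.15, abs=1e-10)
        assert fit.beta3 == pytest.approx(-0.005, abs=1e-12)

    def test_constant_series(self):
        series = make_series(np.full(20, 0.4))
        fit = fit_itsa(build_design(series, event_at(series, 10)), series.values)
        assert fit.beta0 == pytest.approx(0.4)
        for b in (fit.beta1, fit.beta2, fit.beta3):
            assert b == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_on_random_designs(self):
        """OLS coefficients equal a brute-force normal-equations solve."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(12, 51))
            split = int(rng.integers(3, n - 3))
            series = make_series(rng.random(n))
            design = build_design(series, event_at(series, split))
            fit = fit_itsa(design, series.values)
            expected = normal_equations_ols(design.X.to_numpy(), series.values)
            np.testing.assert_allclose(fit.params.to_numpy(), expected, atol=1e-8)

    def test_rank_deficiency_names_columns(self):
        series = make_series(np.linspace(0, 1, 12))
        design = build_design(series, event_at(series, 6))
        X = design.X.copy()
        X["dup"] = X["time"] * 2.0
        broken = ITSADesign(X, design.dates, design.event_index, 0, 365.25)
        with pytest.raises(ValueError, match="dup"):
            fit_itsa(broken, series.values)

    def test_shift_invariance(self):
        """Adding a constant to y moves only the intercept."""
        series, truth = gen_its_series(ITSGenConfig(sigma=0.02, seed=3, beta2=0.1))
        design = build_design(series, PolicyEvent(date=truth.event_date))
        base = fit_itsa(design, series.values)
        shifted = fit_itsa(design, series.values + 5.0)
        assert shifted.beta0 == pytest.approx(base.beta0 + 5.0)
        assert shifted.beta1 == pytest.approx(base.beta1, abs=1e-12)
        assert shifted.beta2 == pytest.approx(base.beta2, abs=1e-10)
        assert shifted.beta3 == pytest.approx(base.beta3, abs=1e-12)

    def test_parameter_recovery_short_monte_carlo(self):
        """Means of the coefficient estimates track the truth over replicates."""
        cfg = dict(beta0=0.5, beta1=0.001, beta2=0.15, beta3=-0.005, sigma=0.05)
        est = []
        for rep in range(60):
            series, truth = gen_its_series(ITSGenConfig(seed=7000 + rep, **cfg))
            design = build_design(series, PolicyEvent(date=truth.event_date))
            fit = fit_itsa(design, series.values)
            est.append([fit.beta0, fit.beta1, fit.beta2, fit.beta3])
        est = np.array(est)
        truth_vec = np.array([0.5, 0.001, 0.15, -0.005])
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - truth_vec) < 3 * mc_se)

    def test_seasonal_terms_absorb_seasonality(self):
        """Matching Fourier order keeps estimates unbiased; omitting it
        inflates residual variance (directional check)."""
        cfg = ITSGenConfig(
            sigma=0.02, seed=21, fourier_amplitudes=((0.05, 0.03),), period=90.0,
            beta0=0.4, beta2=0.1,
        )
        series, truth = gen_its_series(cfg)
        event = PolicyEvent(date=truth.event_date)
        with_k = fit_itsa(build_design(series, event, fourier_k=1, period=90.0), series.values)
        without = fit_itsa(build_design(series, event, fourier_k=0), series.values)
        assert np.var(with_k.residuals) < np.var(without.residuals)
        assert with_k.beta2 == pytest.approx(0.1, abs=0.02)


class TestDurbinWatson:
    def test_alternating_residuals_near_four(self):
        e = np.tile([1.0, -1.0], 50)
        assert durbin_watson(e) >= 3.9

    def test_white_noise_near_two(self):
        e = np.random.default_rng(8).normal(size=2000)
        assert abs(durbin_watson(e) - 2.0) < 0.15

    def test_single_sign_flip_small(self):
        e = np.ones(50)
        e[-1] = -1.0
        assert durbin_watson(e) < 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            durbin_watson(np.zeros(10))

    def test_bounds_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            e = rng.normal(size=rng.integers(3, 40))
            assert 0.0 <= durbin_watson(e) <= 4.0


class TestNeweyWest:
    @staticmethod
    def _design_and_resid(seed=0, n=200, phi=0.0):
        rng = np.random.default_rng(seed)
        series = make_series(np.clip(rng.random(n), 0, 1))
        design = build_design(series, event_at(series, n // 2))
        if phi:
            e = np.zeros(n)
            innov = rng.normal(0, 0.05, n)
            for i in range(1, n):
                e[i] = phi * e[i - 1] + innov[i]
        else:
            e = rng.normal(0, 0.05, n)
        return design, e

    def test_matches_hand_rolled_kernel_sum(self):
        design, e = self._design_and_resid(seed=2)
        for lag in (0, 1, 4, 10):
            got = newey_west_se(design, e, lag)
            expected = bartlett_hac_se(design.X.to_numpy(), e, lag)
            np.testing.assert_allclose(got, expected, rtol=1e-10)

    def test_lag_zero_equals_white_sandwich(self):
        design, e = self._design_and_resid(seed=4)
        X = design.X.to_numpy()
        bread = np.linalg.inv(X.T @ X)
        meat = (X * (e**2)[:, None]).T @ X
        white = np.sqrt(np.diag(bread @ meat @ bread))
        np.testing.assert_allclose(newey_west_se(design, e, 0), white, rtol=1e-10)

    def test_close_to_ols_se_under_iid_noise(self):
        rng = np.random.default_rng(12)
        n = 1000
        series = make_series(np.clip(0.5 + rng.normal(0, 0.05, n), 0, 1))
        design = build_design(series, event_at(series, n // 2))
        fit = fit_itsa(design, series.values)
        ols_se = np.asarray(fit.se if not fit.hac_used else None)
        assert not fit.hac_used  # iid noise should not trip the DW rule
        hac = newey_west_se(design, fit.residuals, 4)
        np.testing.assert_allclose(hac, ols_se, rtol=0.15)

    def test_hac_exceeds_ols_se_under_positive_autocorrelation(self):
        import statsmodels.api as sm

        design, e = self._design_and_resid(seed=6, phi=0.8)
        X = design.X
        y = X.to_numpy() @ np.array([0.5, 0.001, 0.0, 0.0]) + e
        res = sm.OLS(y, X).fit()
        hac = newey_west_se(design, np.asarray(res.resid), default_hac_lag(len(y)))
        assert hac[1] > res.bse.iloc[1]

    def test_lag_bounds(self):
        design, e = self._design_and_resid()
        with pytest.raises(ValueError):
            newey_west_se(design, e, -1)
        with pytest.raises(ValueError):
            newey_west_se(design, e, len(e))


class TestCounterfactual:
    def test_equals_fitted_pre_intervention(self):
        series, truth = gen_its_series(ITSGenConfig(sigma=0.03, seed=9))
        design = build_design(series, PolicyEvent(date=truth.event_date))
        fit = fit_itsa(design, series.values)
        cf = counterfactual(fit)
        np.testing.assert_allclose(cf[: design.event_index], fit.fitted[: design.event_index])

    def test_no_intervention_effect_means_equal_everywhere(self):
        # noiseless, so the fitted level/trend coefficients are exactly zero
        series, truth = gen_its_series(ITSGenConfig(beta2=0.0, beta3=0.0, sigma=0.0, seed=10))
        design = build_design(series, PolicyEvent(date=truth.event_date))
        fit = fit_itsa(design, series.values)
        np.testing.assert_allclose(counterfactual(fit), fit.fitted, atol=1e-8)

    def test_noiseless_gap_at_event_equals_level_shift(self):
        series, truth = gen_its_series(ITSGenConfig(beta2=0.15, sigma=0.0))
        design = build_design(series, PolicyEvent(date=truth.event_date))
        fit = fit_itsa(design, series.values)
        gap = series.values[design.event_index] - counterfactual(fit)[design.event_index]
        assert gap == pytest.approx(0.15, abs=1e-9)


class TestPolicyPanel:
    def test_single_event_full_window_matches_direct_fit(self):
        series, truth = gen_its_series(ITSGenConfig(sigma=0.03, seed=12))
        event = PolicyEvent(date=truth.event_date, name="node1")
        report, fits = run_policy_panel(series, [event], window_days=400)
        direct = fit_itsa(build_design(series, event), series.values)
        assert report.loc[0, "beta2"] == pytest.approx(direct.beta2)
        assert fits["node1"].n_pre == direct.n_pre

    def test_two_far_events_recover_local_effects(self):
        a, ta = gen_its_series(
            ITSGenConfig(beta0=0.3, beta1=0.0, beta2=0.2, beta3=0.0, sigma=0.0, n_pre=40, n_post=40)
        )
        cfg_b = ITSGenConfig(
            beta0=0.5, beta1=0.0, beta2=-0.2, beta3=0.0, sigma=0.0, n_pre=40, n_post=40,
            start=a.dates[-1].date() + pd.Timedelta(days=1).to_pytimedelta(),
        )
        b, tb = gen_its_series(cfg_b)
        stitched = DailyAttitudeSeries(
            dates=a.dates.append(b.dates),
            values=np.concatenate([a.values, b.values]),
            n_comments=np.concatenate([a.n_comments, b.n_comments]),
        )
        events = [
            PolicyEvent(date=ta.event_date, name="up"),
            PolicyEvent(date=tb.event_date, name="down"),
        ]
        report, _ = run_policy_panel(stitched, events, window_days=35)
        by_node = report.set_index("node")
        assert by_node.loc["up", "beta2"] == pytest.approx(0.2, abs=1e-8)
        assert by_node.loc["down", "beta2"] == pytest.approx(-0.2, abs=1e-8)

    def test_event_near_edge_skipped_with_warning(self):
        series, truth = gen_its_series(ITSGenConfig(sigma=0.02, seed=13, n_pre=30, n_post=30))
        edge = PolicyEvent(date=series.dates[2].date(), name="edge")
        with pytest.warns(UserWarning, match="skipped"):
            report, _ = run_policy_panel(series, [edge])
        assert report.empty

    def test_report_columns(self):
        series, truth = gen_its_series(ITSGenConfig(sigma=0.03, seed=14))
        report, _ = run_policy_panel(series, [PolicyEvent(date=truth.event_date)])
        for col in ("node", "beta1", "p1", "beta2", "p2", "beta3", "p3", "dw", "hac_used"):
            assert col in report.columns
        assert ((report["dw"] >= 0) & (report["dw"] <= 4)).all()


def test_default_hac_lag_rule_of_thumb():
    assert default_hac_lag(100) == 4
    assert default_hac_lag(180) == 4
    assert default_hac_lag(30) == 3
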