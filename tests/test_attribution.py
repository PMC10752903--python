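"""Regression attribution: fits, contribution decomposition, correlations."""

import numpy as np
import pandas as pd
import pytest

from gppshift import (AttributionModel, RegionalSeries, SyntheticConfig,
                      correlation_report, fit_attribution,
                      generate_attribution_series)
from gppshift.errors import AlignmentError, PeriodError, SizeError

from oracles import normal_equations_fit, pearson_oracle

YEARS = np.arange(1980, 2017)


def series(values, region="r"):
    return RegionalSeries(np.arange(1980, 1980 + len(values)), np.asarray(values),
                          region=region)


def random_predictors(rng, n=37):
    return {name: series(rng.standard_normal(n), name) for name in
            ("prec", "temp", "co2")}


class TestFit:
    def test_identity_fit(self, rng):
        p = random_predictors(rng)
        res = AttributionModel(p["prec"].copy_with(region="gpp"), p).fit()
        assert res.coefficients["prec"] == pytest.approx(1.0, abs=1e-10)
        assert res.coefficients["temp"] == pytest.approx(0.0, abs=1e-10)
        assert res.coefficients["co2"] == pytest.approx(0.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert np.abs(res.residuals).max() < 1e-10

    def test_noiseless_recovery(self, rng):
        p = random_predictors(rng)
        gpp = series(0.8 * p["prec"].values - 0.2 * p["temp"].values
                     + 0.3 * p["co2"].values, "gpp")
        res = AttributionModel(gpp, p).fit()
        assert res.coefficients["prec"] == pytest.approx(0.8, abs=1e-10)
        assert res.coefficients["temp"] == pytest.approx(-0.2, abs=1e-10)
        assert res.coefficients["co2"] == pytest.approx(0.3, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        p = random_predictors(rng, n=20)
        gpp = series(rng.standard_normal(20), "gpp")
        res = AttributionModel(gpp, p).fit()
        names = list(p)
        beta = normal_equations_fit(np.column_stack([p[k].values for k in names]),
                                    gpp.values)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        for i, name in enumerate(names):
            assert res.coefficients[name] == pytest.approx(beta[i + 1], abs=1e-8)

    def test_residuals_sum_to_zero(self, rng):
        p = random_predictors(rng)
        gpp = series(rng.standard_normal(37), "gpp")
        res = AttributionModel(gpp, p).fit()
        assert abs(res.residuals.sum()) < 1e-10

    def test_predictor_order_irrelevant(self, rng):
        p = random_predictors(rng)
        gpp = series(rng.standard_normal(37), "gpp")
        r1 = AttributionModel(gpp, p).fit()
        reordered = {k: p[k] for k in ("co2", "prec", "temp")}
        r2 = AttributionModel(gpp, reordered).fit()
        for name in p:
            assert r1.coefficients[name] == pytest.approx(r2.coefficients[name],
                                                          abs=1e-10)
        c1 = r1.contributions(range(1990, 1999), range(1999, 2008))
        c2 = r2.contributions(range(1990, 1999), range(1999, 2008))
        assert c1["total"] == pytest.approx(c2["total"], abs=1e-12)

    def test_mismatched_years(self, rng):
        p = random_predictors(rng)
        gpp = RegionalSeries(np.arange(1981, 2018), rng.standard_normal(37))
        with pytest.raises(AlignmentError):
            AttributionModel(gpp, p)

    def test_too_few_years(self, rng):
        p = {k: RegionalSeries(np.arange(2000, 2005), rng.standard_normal(5), k)
             for k in ("prec", "temp", "co2")}
        gpp = RegionalSeries(np.arange(2000, 2005), rng.standard_normal(5))
        with pytest.raises(SizeError):
            AttributionModel(gpp, p)


class TestContributions:
    def test_additivity_exact(self, rng):
        for _ in range(10):
            p = random_predictors(rng)
            gpp = series(rng.standard_normal(37), "gpp")
            res = AttributionModel(gpp, p).fit()
            c = res.contributions(range(1990, 1999), range(1999, 2008))
            assert c["total"] == pytest.approx(c["prec"] + c["temp"] + c["co2"],
                                               abs=1e-12)

    def test_total_equals_reconstructed_difference(self, rng):
        """The summed contributions equal the P2-P1 change of the fitted
        reconstruction (the intercept cancels)."""
        p = random_predictors(rng)
        gpp = series(rng.standard_normal(37), "gpp")
        res = AttributionModel(gpp, p).fit()
        p1 = list(range(1990, 1999))
        p2 = list(range(1999, 2008))
        c = res.contributions(p1, p2)
        fitted = pd.Series(res.fittedvalues, index=YEARS)
        recon_diff = fitted[p2].mean() - fitted[p1].mean()
        assert c["total"] == pytest.approx(recon_diff, abs=1e-12)

    def test_unchanged_predictor_contributes_zero(self, rng):
        p = random_predictors(rng)
        p["temp"] = series(np.ones(37) * 0.3 + np.r_[np.linspace(-1, 1, 18),
                                                     np.linspace(1, -1, 19)])
        gpp = series(rng.standard_normal(37), "gpp")
        res = AttributionModel(gpp, p).fit()
        p1 = [1985, 1990]
        p2 = [1995, 2000]  # symmetric triangle: equal period means
        c = res.contributions(p1, p2)
        delta = p["temp"].period_mean(p2) - p["temp"].period_mean(p1)
        assert c["temp"] == pytest.approx(res.coefficients["temp"] * delta, abs=1e-12)

    def test_pure_step_attribution(self):
        prec = np.r_[np.full(19, 0.5), np.full(18, -0.5)]
        jitter = 1e-6 * np.sin(np.arange(37))  # avoid exact collinearity
        p = {"prec": series(prec, "prec"),
             "temp": series(np.cos(np.arange(37.0)), "temp"),
             "co2": series(np.linspace(-1, 1, 37) + jitter, "co2")}
        gpp = series(prec, "gpp")
        res = AttributionModel(gpp, p).fit()
        c = res.contributions(range(1990, 1999), range(1999, 2008))
        assert c["prec"] == pytest.approx(-1.0, abs=1e-6)
        assert c["temp"] == pytest.approx(0.0, abs=1e-6)
        assert c["total"] == pytest.approx(-1.0, abs=1e-6)

    def test_overlapping_periods_rejected(self, rng):
        p = random_predictors(rng)
        res = AttributionModel(series(rng.standard_normal(37), "gpp"), p).fit()
        with pytest.raises(PeriodError):
            res.contributions([1990, 1991], [1991, 1992])


class TestSyntheticRecovery:
    def test_coefficient_recovery_bias(self):
        """Seed-averaged coefficients are unbiased (< 0.03) at n = 37,
        noise SD 0.3 (the generator's default coupling)."""
        n_seeds = 300
        est = np.zeros((n_seeds, 3))
        for seed in range(n_seeds):
            cfg = SyntheticConfig(seed=seed)
            data, truth = generate_attribution_series(cfg)
            res = fit_attribution(data["gpp"], data["prec"], data["temp"],
                                  data["co2"])
            est[seed] = [res.coefficients[k] for k in ("prec", "temp", "co2")]
        bias = est.mean(axis=0) - np.array([0.8, -0.2, 0.3])
        assert np.abs(bias).max() < 0.03

    def test_contribution_recovery(self):
        """Seed-averaged recovered contributions match the generator truth
        within +-0.2."""
        n_seeds = 100
        rec = []
        cfg0 = SyntheticConfig(seed=0)
        truth = None
        for seed in range(n_seeds):
            cfg = SyntheticConfig(seed=seed)
            data, truth = generate_attribution_series(cfg)
            res = fit_attribution(data["gpp"], data["prec"], data["temp"],
                                  data["co2"])
            periods = truth.contribution_periods
            c = res.contributions(periods["p1"], periods["p2"])
            rec.append([c["prec"], c["temp"], c["co2"]])
        mean_rec = np.mean(rec, axis=0)
        expected = [truth.contributions[k] for k in ("prec", "temp", "co2")]
        assert np.abs(mean_rec - expected).max() < 0.2


class TestCorrelationReport:
    def test_self_and_negation(self, rng):
        gpp = series(rng.standard_normal(20), "gpp")
        report = correlation_report(gpp, {
            "self": gpp.copy_with(region="self"),
            "neg": gpp.copy_with(values=-gpp.values, region="neg"),
        })
        assert report.loc["self", "r"] == pytest.approx(1.0)
        assert report.loc["neg", "r"] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        gpp = series(rng.standard_normal(25), "gpp")
        drv = series(rng.standard_normal(25), "prec")
        report = correlation_report(gpp, {"prec": drv})
        assert report.loc["prec", "r"] == pytest.approx(
            pearson_oracle(gpp.values, drv.values), abs=1e-12)

    def test_subperiod_option(self, rng):
        gpp = series(rng.standard_normal(30), "gpp")
        drv = series(rng.standard_normal(30), "prec")
        sub = correlation_report(gpp, {"prec": drv}, period=range(1990, 2006))
        shared = np.arange(1990, 2006)
        x = gpp.values[np.isin(gpp.years, shared)]
        y = drv.values[np.isin(drv.years, shared)]
        assert sub.loc["prec", "r"] == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        assert sub.loc["prec", "n"] == 16

    def test_too_few_points(self, rng):
        gpp = series(rng.standard_normal(10), "gpp")
        short = RegionalSeries(np.array([1980, 1981]), np.array([0.0, 1.0]))
        with pytest.raises(SizeError):
            correlation_report(gpp, {"short": short})

    def test_effective_sample_size_reduces_significance(self):
        years = np.arange(1980, 2016)
        trend = np.linspace(-1, 1, 36)
        gpp = RegionalSeries(years, trend + 0.05 * np.sin(years * 1.7))
        drv = RegionalSeries(years, trend + 0.05 * np.cos(years * 2.3))
        plain = correlation_report(gpp, {"d": drv})
        adj = correlation_report(gpp, {"d": drv}, effective_sample_size=True)
        assert adj.loc["d", "p_value"] >= plain.loc["d", "p_value"]
        assert adj.loc["d", "n"] < plain.loc["d", "n"]
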