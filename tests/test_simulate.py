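"""Synthetic-world generator: shapes, determinism, conservation, recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from salmonsize.io import SST_REGIONS
from salmonsize.simulate import (
    CovariateConfig,
    TruthConfig,
    calibrate_sigma_year,
    recovery_world,
    simulate_covariates,
    simulate_population,
    true_anomaly_series,
)


class TestCovariates:
    def test_shape(self):
        df = simulate_covariates((1990, 2009), seed=1)
        assert len(df) == 20
        sst_cols = [c for c in df.columns if c.startswith("sst_")]
        assert len(sst_cols) == len(SST_REGIONS) * 12

    def test_determinism(self):
        a = simulate_covariates((1990, 2009), seed=3)
        b = simulate_covariates((1990, 2009), seed=3)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_covariates((1990, 2009), seed=4)
        assert not a.equals(c)

    def test_too_short_span(self):
        with pytest.raises(ValueError):
            simulate_covariates((1990, 1995), seed=0)

    def test_pink_chum_confounding(self):
        """Pink and chum series are strongly correlated by construction
        (shared factor + shared trend), reproducing the real collinearity."""
        rs = []
        for seed in range(20):
            df = simulate_covariates((1960, 2009), seed=seed)
            rs.append(np.corrcoef(df["pink_abund"], df["chum_abund"])[0, 1])
        rs = np.array(rs)
        assert rs.mean() > 0.7
        assert (rs >= 0.6).mean() >= 0.9

    def test_winter_colder_than_summer(self):
        df = simulate_covariates((1990, 2009), seed=0)
        assert df["sst_bering_sea_02"].mean() < df["sst_bering_sea_08"].mean()


class TestPopulation:
    def test_conservation(self, small_world):
        """Brood-table counts per (river, return year) match the run
        summary exactly, split by catch and escapement."""
        world = small_world["world"]
        brood = world["brood_table"].copy()
        from salmonsize.ages import assign_brood_year, parse_age_code

        brood["return_year"] = [
            by + parse_age_code(a).total_age
            for by, a in zip(brood["brood_year"], brood["age_code"])
        ]
        got = brood.groupby(["river", "return_year"])[["catch_count", "escapement_count"]].sum()
        run = world["run_summary"].set_index(["river", "return_year"])
        joined = got.join(run, how="inner")
        np.testing.assert_allclose(joined["catch_count"], joined["catch_total"], rtol=1e-12)
        np.testing.assert_allclose(joined["escapement_count"], joined["escapement_total"], rtol=1e-12)

    def test_reproducibility_byte_identical(self):
        truth = TruthConfig(rivers=("wood",), brood_years=(1990, 2001),
                            mean_return=1e4, sampling_frac_catch=0.02,
                            sampling_frac_escapement=0.02, seed=5)
        covars = simulate_covariates((1985, 2010), seed=5)
        a = simulate_population(truth, covars)
        b = simulate_population(truth, covars)
        for key in ("al_samples", "brood_table", "run_summary"):
            pd.testing.assert_frame_equal(a[key], b[key])
        assert a["truth"] == b["truth"]

    def test_degenerate_noise_gives_exact_lengths(self):
        """With all dispersion and all effects off, every fish of age a in
        river r has exactly the baseline length."""
        truth = TruthConfig(
            rivers=("wood",), brood_years=(1990, 2001), mean_return=2000,
            return_cv=0.0, sigma_within=0.0, sigma_year=0.0,
            trend_mm_per_year=0.0, beta={}, gamma={},
            selectivity_slope=0.0,
            sampling_frac_catch=0.05, sampling_frac_escapement=0.05, seed=2,
        )
        covars = simulate_covariates((1985, 2010), seed=2)
        world = simulate_population(truth, covars)
        al = world["al_samples"]
        for age, grp in al.groupby("age_code"):
            assert (grp["length_mm"] == truth.baseline_mm[age] + truth.river_offset_mm["wood"]).all()

    def test_zero_selectivity_equalises_sources(self):
        """Unselective harvest: catch and escapement sample means agree
        within Monte-Carlo error."""
        truth = TruthConfig(
            rivers=("wood",), brood_years=(1990, 2005), mean_return=5e4,
            selectivity_slope=0.0, sampling_frac_catch=0.02,
            sampling_frac_escapement=0.02, seed=3,
        )
        covars = simulate_covariates((1985, 2015), seed=3)
        al = simulate_population(truth, covars)["al_samples"]
        by_src = al.groupby(["age_code", "source"])["length_mm"].agg(["mean", "count"])
        for age in truth.age_groups:
            c = by_src.loc[(age, "catch")]
            e = by_src.loc[(age, "escapement")]
            se = truth.sigma_within * np.sqrt(1 / c["count"] + 1 / e["count"])
            assert abs(c["mean"] - e["mean"]) < 4 * se

    def test_positive_selectivity_biases_catch_large(self):
        truth = TruthConfig(rivers=("wood",), brood_years=(1990, 2005), mean_return=5e4,
                            selectivity_slope=0.05, sampling_frac_catch=0.02,
                            sampling_frac_escapement=0.02, seed=3)
        covars = simulate_covariates((1985, 2015), seed=3)
        al = simulate_population(truth, covars)["al_samples"]
        means = al.groupby("source")["length_mm"].mean()
        assert means["catch"] > means["escapement"] + 5

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TruthConfig(age_groups=("1.2", "9.9"))
        with pytest.raises(ValueError):
            TruthConfig(harvest_rate=1.5)
        with pytest.raises(ValueError):
            TruthConfig(baseline_mm={"1.2": 0.0}, age_groups=("1.2",))


class TestTruthRecovery:
    def test_beta_pink_recovery_single_replicate(self):
        """Regressing the simulated annual anomaly on lagged pink abundance
        recovers the injected -2 mm per million within 2 SE (n=50)."""
        cov_cfg = CovariateConfig(pink_mean=60.0, pink_sd=7.5, pink_trend=0.0,
                                  chum_mean=40.0, chum_sd=6.0, chum_trend=0.0)
        covars = simulate_covariates((1960, 2013), seed=9, cfg=cov_cfg)
        truth = TruthConfig(brood_years=(1958, 2006), trend_mm_per_year=0.0,
                            beta={"pink_lag1": -2.0}, gamma={}, sigma_year=20.0, seed=9)
        anom = true_anomaly_series(truth, covars, seed=21)
        pink = covars.set_index("year")["pink_abund"].rename(lambda y: y + 1)
        years = anom.index.intersection(pink.index)[:50]
        x = pink.loc[years] - pink.loc[years].mean()
        fit = sm.OLS(anom.loc[years].to_numpy(), sm.add_constant(x.to_numpy())).fit()
        assert abs(fit.params[1] - (-2.0)) < 2 * fit.bse[1]

    def test_calibrated_r2(self):
        """sigma_year calibration hits the target explainable-variance share."""
        truth, covars = recovery_world(n_years=58, seed=4)
        anoms = [true_anomaly_series(truth, covars, seed=100 + k) for k in range(30)]
        det = true_anomaly_series(
            TruthConfig(**{**truth.__dict__, "sigma_year": 0.0}), covars, seed=0
        )
        resid_var = np.mean([np.var(a - det) for a in anoms])
        r2 = np.var(det) / (np.var(det) + resid_var)
        assert 0.5 < r2 < 0.7
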