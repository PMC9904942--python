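"""All-subsets AIC selection, variance partitioning, partial effects."""

import numpy as np
import pandas as pd
import pytest

from salmonsize.covariates import PredictorTable
from salmonsize.model_selection import (
    enumerate_term_sets,
    partial_effects,
    partition_variance,
    select_model,
)


def _table(frame_dict, scalers=None):
    frame = pd.DataFrame(frame_dict)
    return PredictorTable(frame=frame, scalers=scalers or {})


def _orthogonal_design(n=64, seed=0):
    """Exactly orthogonal, mean-zero, unit-SD predictors via QR against 1."""
    rng = np.random.default_rng(seed)
    a = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    q, _ = np.linalg.qr(a)
    q = q[:, 1:]  # orthogonal to the intercept -> exactly mean zero
    return q / q.std(axis=0, ddof=0)


class TestEnumeration:
    def test_marginality_and_exclusions(self):
        sets = enumerate_term_sets(
            ["a_z", "b_z"], quadratic=["a_z2"], exclusions=[frozenset(("a_z", "b_z"))]
        )
        as_sets = [set(s) for s in sets]
        assert {"a_z", "b_z"} not in as_sets                 # excluded pair
        assert {"a_z2"} not in as_sets                       # quadratic needs parent
        assert {"a_z", "a_z2"} in as_sets
        assert set() in as_sets                              # intercept-only
        assert len(sets) == 4  # {}, {a}, {a, a2}, {b}

    def test_interaction_needs_both_parents(self):
        sets = enumerate_term_sets(["regime", "s_z"], interactions=["regime_x_s_z"])
        as_sets = [set(s) for s in sets]
        assert {"regime_x_s_z"} not in as_sets
        assert {"regime", "s_z", "regime_x_s_z"} in as_sets


class TestSelection:
    def test_perfect_linear(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        pt = _table({"anomaly": 3.0 * x, "x_z": x})
        fit = select_model(pt, linear=["x_z"], quadratic=[], interactions=[])
        assert fit.terms == ("x_z",)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.params["x_z"] == pytest.approx(3.0)

    def test_refit_reproduces_aic(self):
        """The statsmodels refit of the winning term set reproduces the
        search AIC exactly."""
        rng = np.random.default_rng(1)
        x1, x2 = rng.normal(size=(2, 60))
        pt = _table({"anomaly": 2 * x1 + rng.normal(size=60), "x1_z": x1, "x2_z": x2})
        fit = select_model(pt, linear=["x1_z", "x2_z"], quadratic=[], interactions=[])
        best_row = fit.candidates.loc[fit.candidates["delta_aic"] == 0.0].iloc[0]
        assert fit.aic == pytest.approx(best_row["aic"], abs=1e-9)
        assert (fit.candidates["delta_aic"] >= 0).all()

    def test_pure_noise_prefers_intercept(self):
        """With a pure-noise response AIC keeps the intercept-only model in
        the majority of replicates (~58%: per-predictor false-inclusion
        under AIC is ~16%, so (0.84)^3 ~ 0.59 with three null predictors)."""
        rng = np.random.default_rng(7)
        hits = 0
        nrep = 200
        for _ in range(nrep):
            n = 60
            pt = _table({
                "anomaly": rng.normal(size=n),
                "x1_z": rng.normal(size=n),
                "x2_z": rng.normal(size=n),
                "x3_z": rng.normal(size=n),
            })
            fit = select_model(pt, linear=["x1_z", "x2_z", "x3_z"], quadratic=[], interactions=[])
            hits += len(fit.terms) == 0
        assert hits / nrep > 0.5

    def test_strong_signal_recovers_terms(self):
        """Response b1*x1 + b2*x2^2 + small noise: the generating terms are
        in the selected model in >=90% of replicates."""
        rng = np.random.default_rng(8)
        ok = 0
        nrep = 100
        for _ in range(nrep):
            n = 60
            x1, x2 = rng.normal(size=(2, n))
            y = 2.0 * x1 + 1.5 * x2**2 + rng.normal(size=n)
            pt = _table({"anomaly": y, "x1_z": x1, "x2_z": x2,
                         "x1_z2": x1**2, "x2_z2": x2**2})
            fit = select_model(pt, linear=["x1_z", "x2_z"],
                               quadratic=["x1_z2", "x2_z2"], interactions=[])
            ok += {"x1_z", "x2_z", "x2_z2"} <= set(fit.terms)
        assert ok / nrep >= 0.9

    def test_exclusion_honoured(self):
        rng = np.random.default_rng(9)
        x1 = rng.normal(size=60)
        x2 = 0.9 * x1 + 0.44 * rng.normal(size=60)
        pt = _table({"anomaly": 2 * x1 + rng.normal(size=60), "x1_z": x1, "x2_z": x2})
        fit = select_model(pt, linear=["x1_z", "x2_z"], quadratic=[], interactions=[],
                           exclusions=[frozenset(("x1_z", "x2_z"))])
        assert not {"x1_z", "x2_z"} <= set(fit.terms)
        for terms in fit.candidates["terms"]:
            assert not ("x1_z" in terms and "x2_z" in terms)

    def test_too_few_years(self):
        x = np.array([1.0, 2.0, 4.0])
        pt = _table({"anomaly": x, "x_z": x, "x_z2": x**2})
        with pytest.raises(ValueError):
            select_model(pt, linear=["x_z"], quadratic=["x_z2"], interactions=[])


class TestPartition:
    def test_orthogonal_shares_sum_to_r2(self):
        q = _orthogonal_design()
        y = 2 * q[:, 0] + 1 * q[:, 1] + 0.5 * np.random.default_rng(0).normal(size=64)
        pt = _table({"anomaly": y, "a_z": q[:, 0], "b_z": q[:, 1], "c_z": q[:, 2]})
        fit = select_model(pt, linear=["a_z", "b_z", "c_z"], quadratic=[], interactions=[])
        shares = partition_variance(fit)
        assert shares.sum() / 100.0 == pytest.approx(fit.r2, abs=1e-6)

    def test_single_predictor_share_equals_r2(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        pt = _table({"anomaly": 2 * x + rng.normal(size=50), "x_z": x})
        fit = select_model(pt, linear=["x_z"], quadratic=[], interactions=[])
        shares = partition_variance(fit)
        assert shares["x"] / 100.0 == pytest.approx(fit.r2)

    def test_null_predictor_share_near_zero(self):
        q = _orthogonal_design(seed=2)
        rng = np.random.default_rng(2)
        y = 3 * q[:, 0] + 0.3 * rng.normal(size=64)
        pt = _table({"anomaly": y, "a_z": q[:, 0], "b_z": q[:, 1]})
        fit = select_model(pt, linear=["a_z", "b_z"], quadratic=[], interactions=[])
        shares = partition_variance(fit)
        if "b" in shares:
            assert shares["b"] < 2.0
        assert shares["a"] > 90.0 * fit.r2 / 100.0 * 0.9  # dominant predictor


class TestPartialEffects:
    @staticmethod
    def _fit(curved=False):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = (2.0 * x - 1.5 * x**2 if curved else 2.0 * x) + 0.1 * rng.normal(size=80)
        pt = _table({"anomaly": y, "x_z": x, "x_z2": x**2}, scalers={"x": (10.0, 2.0)})
        quad = ["x_z2"] if curved else []
        return select_model(pt, linear=["x_z"], quadratic=quad, interactions=[])

    def test_linear_effect_is_straight_line(self):
        fit = self._fit(curved=False)
        eff = partial_effects(fit, "x", grid=np.linspace(-2, 2, 9))
        slopes = np.diff(eff["effect"]) / np.diff(eff["z"])
        np.testing.assert_allclose(slopes, fit.params["x_z"], rtol=1e-6)

    def test_quadratic_vertex(self):
        fit = self._fit(curved=True)
        assert "x_z2" in fit.terms
        b1, b2 = fit.params["x_z"], fit.params["x_z2"]
        eff = partial_effects(fit, "x", grid=np.linspace(-2, 2, 401))
        vertex = eff["z"].iloc[eff["effect"].idxmax()]
        assert vertex == pytest.approx(-b1 / (2 * b2), abs=0.02)
        assert eff["x"].iloc[0] == pytest.approx(10.0 + 2.0 * -2.0)  # natural units

    def test_ci_widens_at_edges(self):
        fit = self._fit(curved=False)
        eff = partial_effects(fit, "x", grid=np.linspace(-3, 3, 31))
        width = eff["ci_high"] - eff["ci_low"]
        assert width.iloc[0] > width.iloc[15]
        assert width.iloc[-1] > width.iloc[15]
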