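"""All-subsets AIC regression for size-at-age anomalies.

Candidate models are every subset of the admissible terms that honours

* collinearity constraints — no two predictors with |r| above the screen
  threshold in the same model, and
* marginality — a quadratic term only together with its linear term, an
  interaction only with both main effects.

Each candidate is an ordinary least-squares fit with intercept, ranked by
AIC (AICc optional).  Ties are broken by fewer terms, then by term names,
so selection is deterministic.  The best model is refit with statsmodels
to provide standard errors, confidence intervals and partial effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from salmonsize.covariates import PredictorTable

__all__ = ["ModelFit", "enumerate_term_sets", "select_model", "partition_variance", "partial_effects"]


@dataclass
class ModelFit:
    """A selected regression: terms, coefficients, AIC and diagnostics."""

    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    aic: float
    r2: float
    candidates: pd.DataFrame        # all models with delta AIC < 2
    n_candidates: int               # size of the searched model space
    residuals: pd.Series
    result: object                  # statsmodels OLSResults of the refit
    predictors: PredictorTable | None = field(default=None, repr=False)


def _quad_parent(term: str) -> str:
    return term[:-3] + "_z"


def _interaction_parents(term: str) -> tuple[str, str]:
    # "regime_x_<base>_z" -> ("regime", "<base>_z")
    return "regime", term[len("regime_x_"):]


def enumerate_term_sets(
    linear: list[str],
    quadratic: list[str] = (),
    interactions: list[str] = (),
    exclusions: list[frozenset] = (),
) -> list[tuple[str, ...]]:
    """All admissible term subsets (including the intercept-only empty set).

    ``linear`` are standardised columns (``regime`` counts as linear);
    ``quadratic`` columns require their linear parent; ``interactions``
    require both parents.  ``exclusions`` are mutually exclusive pairs of
    linear terms from the collinearity screen.
    """
    linear = list(linear)
    sets: list[tuple[str, ...]] = []
    for k in range(len(linear) + 1):
        for lin in combinations(linear, k):
            lin_set = set(lin)
            if any(pair <= lin_set for pair in exclusions):
                continue
            quads_ok = [q for q in quadratic if _quad_parent(q) in lin_set]
            inters_ok = [t for t in interactions if set(_interaction_parents(t)) <= lin_set]
            extras = quads_ok + inters_ok
            for m in range(len(extras) + 1):
                for extra in combinations(extras, m):
                    sets.append(tuple(lin) + extra)
    return sets


def _ols_aic(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """(aic, r2) of an OLS fit with intercept already in X."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    p = X.shape[1]
    # statsmodels loglike convention so a refit reproduces the AIC exactly
    llf = -n / 2.0 * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    return float(-2 * llf + 2 * p), (1.0 - rss / tss if tss > 0 else 0.0)


def select_model(
    predictors: PredictorTable,
    linear: list[str] | None = None,
    quadratic: list[str] | None = None,
    interactions: list[str] | None = None,
    exclusions: list[frozenset] = (),
    response: str = "anomaly",
    use_aicc: bool = False,
) -> ModelFit:
    """Exhaustive AIC search over admissible term subsets.

    Returns the best model (refit with statsmodels for inference) together
    with the table of all candidates within delta AIC < 2 of the best.
    """
    frame = predictors.frame
    if linear is None:
        linear = [c for c in predictors.linear_terms if not c.startswith("regime_x_")]
    if quadratic is None:
        quadratic = [q for q in predictors.quadratic_terms if _quad_parent(q) in linear]
    if interactions is None:
        interactions = [c for c in frame.columns if c.startswith("regime_x_") and c[len("regime_x_"):] in linear]
        if interactions and "regime" not in linear:
            linear = list(linear) + ["regime"]

    y = frame[response].to_numpy(dtype=float)
    n = len(y)
    term_sets = enumerate_term_sets(linear, quadratic, interactions, exclusions)
    max_terms = max(len(t) for t in term_sets)
    if n <= max_terms + 1:
        raise ValueError(f"{n} years cannot support models with up to {max_terms} terms")

    cols = {c: frame[c].to_numpy(dtype=float) for c in set().union(*map(set, term_sets)) or set()}
    ones = np.ones(n)

    records = []
    for terms in term_sets:
        X = np.column_stack([ones] + [cols[t] for t in terms]) if terms else ones[:, None]
        aic, r2 = _ols_aic(y, X)
        if use_aicc:
            k = X.shape[1] + 1  # + residual variance
            aic = aic + 2.0 * k * (k + 1) / (n - k - 1)
        records.append((aic, len(terms), terms, r2))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    best_aic, _, best_terms, _ = records[0]

    cand = pd.DataFrame(
        [
            {"terms": " + ".join(t) if t else "(intercept)", "n_terms": k,
             "aic": a, "delta_aic": a - best_aic, "r2": r2}
            for a, k, t, r2 in records if a - best_aic < 2.0
        ]
    )

    X = sm.add_constant(frame[list(best_terms)], has_constant="add") if best_terms else pd.DataFrame(
        {"const": np.ones(n)}, index=frame.index
    )
    res = sm.OLS(frame[response], X).fit()
    return ModelFit(
        terms=best_terms,
        params=res.params,
        bse=res.bse,
        aic=float(res.aic) if not use_aicc else best_aic,
        r2=float(res.rsquared),
        candidates=cand,
        n_candidates=len(records),
        residuals=res.resid,
        result=res,
        predictors=predictors,
    )


def _base_of(term: str) -> str:
    """Natural predictor behind a term column."""
    if term.startswith("regime_x_"):
        return _base_of(term[len("regime_x_"):])
    if term.endswith("_z2"):
        return term[:-3]
    if term.endswith("_z"):
        return term[:-2]
    return term


def partition_variance(fit: ModelFit, predictors: PredictorTable | None = None) -> pd.Series:
    """Percent of response variance attributed to each predictor.

    The share of predictor P is the drop in R^2 when all of P's terms
    (linear, quadratic, interactions) are removed from the selected model
    and the reduced model is refit.  Shares sum to the full R^2 only for
    orthogonal predictors.
    """
    predictors = predictors or fit.predictors
    frame = predictors.frame
    y = frame["anomaly"].to_numpy(dtype=float)
    n = len(y)
    ones = np.ones(n)

    def _r2(terms: tuple[str, ...]) -> float:
        X = np.column_stack([ones] + [frame[t].to_numpy(dtype=float) for t in terms]) if terms else ones[:, None]
        return _ols_aic(y, X)[1]

    full = _r2(fit.terms)
    bases = sorted({_base_of(t) for t in fit.terms})
    shares = {}
    for base in bases:
        reduced = tuple(t for t in fit.terms if _base_of(t) != base)
        shares[base] = 100.0 * (full - _r2(reduced))
    return pd.Series(shares, name="variance_share_pct")


def partial_effects(
    fit: ModelFit,
    predictor: str,
    grid: np.ndarray | None = None,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Partial-effect curve with 95% CI for one predictor.

    Other predictors are held at zero (their standardised mean); the grid
    is in standardised units with natural-unit values alongside when the
    scaler is known.
    """
    predictors = fit.predictors
    frame = predictors.frame
    zcol = predictor if predictor.endswith("_z") else predictor + "_z"
    if zcol not in [t for t in fit.terms] and zcol + "2" not in fit.terms:
        raise ValueError(f"{predictor!r} is not in the selected model")
    if grid is None:
        lo, hi = frame[zcol].min(), frame[zcol].max()
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)

    design = pd.DataFrame(0.0, index=range(len(grid)), columns=list(fit.terms))
    if zcol in design.columns:
        design[zcol] = grid
    if zcol + "2" in design.columns:
        design[zcol + "2"] = grid ** 2
    X = sm.add_constant(design, has_constant="add")
    pred = fit.result.get_prediction(X)
    ci = pred.conf_int(alpha=0.05)
    out = pd.DataFrame({
        "z": grid,
        "effect": pred.predicted_mean,
        "ci_low": ci[:, 0],
        "ci_high": ci[:, 1],
    })
    base = zcol[:-2]
    if predictors is not None and base in predictors.scalers:
        mu, sd = predictors.scalers[base]
        out.insert(1, base, mu + sd * grid)
    return out
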