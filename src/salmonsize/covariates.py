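"""Predictor assembly for the size-at-age covariate model.

Builds the return-year design table: intra- and interspecific competition
(Bristol Bay sockeye run size, North Pacific pink/chum abundance lagged 1-2
years), seasonal sea surface temperatures (winter Jan-Mar of the return
year near the Aleutians; summer Jul-Sep of the previous year in the Bering
Sea), freshwater rearing temperature, fishery selection differentials
lagged about one generation (4 and 5 years and their average), and the
1988/89 climate-regime factor.

Continuous predictors are standardised (z-scores over the fitted span) and
quadratic columns are squares of the standardised columns, which keeps
linear and quadratic terms nearly orthogonal; the scalers are stored for
back-transformation to natural units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["seasonal_sst", "build_predictors", "screen_collinearity", "choose_competitor", "PredictorTable"]

SEASON_MONTHS = {"winter": (1, 2, 3), "summer": (7, 8, 9)}


def seasonal_sst(covars: pd.DataFrame, season: str, region: str, lag: int = 0) -> pd.Series:
    """Seasonal mean SST for a region, optionally lagged.

    For return year ``y`` the value is the mean of the monthly SSTs of
    calendar year ``y - lag`` over Jan-Mar (winter) or Jul-Sep (summer).
    A missing month column or cell raises an error naming (region, year,
    month).
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"season must be one of {sorted(SEASON_MONTHS)}, got {season!r}")
    months = SEASON_MONTHS[season]
    cols = [f"sst_{region}_{m:02d}" for m in months]
    missing = [c for c in cols if c not in covars.columns]
    if missing:
        raise KeyError(f"missing monthly SST column(s) for region {region!r}: {missing}")
    base = covars.set_index("year")[cols]
    if base.isna().any().any():
        bad = [(int(y), c) for y, row in base.iterrows() for c in cols if pd.isna(row[c])]
        raise ValueError(f"missing SST values for region {region!r}: {bad[:5]}")
    seasonal = base.mean(axis=1)
    out = pd.Series(seasonal.to_numpy(), index=seasonal.index + lag)
    out.name = f"sst_{season}_{region}" + (f"_lag{lag}" if lag else "")
    out.index.name = "year"
    return out


@dataclass
class PredictorTable:
    """Design table for the covariate model.

    ``frame`` is indexed by return year with the response column
    ``anomaly`` (mm), raw predictor columns, standardised copies suffixed
    ``_z`` and quadratic columns suffixed ``_z2``.  ``scalers`` maps each
    raw predictor to its (mean, sd) over the fitted span.
    """

    frame: pd.DataFrame
    scalers: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def linear_terms(self) -> list[str]:
        return [c for c in self.frame.columns if c.endswith("_z")]

    @property
    def quadratic_terms(self) -> list[str]:
        return [c for c in self.frame.columns if c.endswith("_z2")]

    def backtransform(self, term: str, coef: float) -> float:
        """Convert a standardised coefficient to natural units.

        Linear: per raw predictor unit; quadratic: per squared centred
        unit.
        """
        if term.endswith("_z2"):
            base = term[:-3]
            return coef / self.scalers[base][1] ** 2
        if term.endswith("_z"):
            base = term[:-2]
            return coef / self.scalers[base][1]
        return coef


def _standardize(frame: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, dict]:
    scalers = {}
    for c in cols:
        mu = float(frame[c].mean())
        sd = float(frame[c].std(ddof=0))
        if sd == 0:
            raise ValueError(f"predictor {c!r} is constant over the fitted span")
        frame[c + "_z"] = (frame[c] - mu) / sd
        scalers[c] = (mu, sd)
    return frame, scalers


def build_predictors(
    covars: pd.DataFrame,
    anomalies: pd.Series | pd.DataFrame,
    cfg: dict | None = None,
    seldiff: pd.Series | None = None,
) -> PredictorTable:
    """Assemble the return-year predictor table.

    Parameters
    ----------
    covars
        Covariate table (one row per year) as read by
        :func:`salmonsize.io.read_covariates`.
    anomalies
        Return-year mean size-at-age anomaly series (mm), or the frame
        produced by :func:`salmonsize.metrics.size_at_age_anomalies`.
    cfg
        Options: ``regime_split_year`` (default 1989), ``lake_temp_lag``
        (default 4, roughly the freshwater rearing period before return),
        ``quadratic`` (predictors given quadratic columns; defaults to all
        continuous predictors).
    seldiff
        Bay-wide selection-differential series by return year (mm).  If
        omitted, per-river ``seldiff_*`` columns of ``covars`` are
        averaged; if none exist the selection predictors are skipped.
    """
    cfg = cfg or {}
    split = int(cfg.get("regime_split_year", 1989))
    lake_lag = int(cfg.get("lake_temp_lag", 4))

    if isinstance(anomalies, pd.DataFrame):
        anomalies = anomalies["mean_anomaly_mm"]
    resp = anomalies.copy()
    resp.index = resp.index.astype(int)

    by_year = covars.set_index("year")
    cols: dict[str, pd.Series] = {}
    cols["sockeye_run"] = by_year["sockeye_run"]
    for lag in (1, 2):
        cols[f"pink_lag{lag}"] = by_year["pink_abund"].rename(lambda y: y + lag)
        cols[f"chum_lag{lag}"] = by_year["chum_abund"].rename(lambda y: y + lag)
    cols["sst_winter_aleutians"] = seasonal_sst(covars, "winter", "aleutians", lag=0)
    cols["sst_summer_bering_lag1"] = seasonal_sst(covars, "summer", "bering_sea", lag=1)
    if "lake_temp" in by_year.columns and by_year["lake_temp"].notna().any():
        cols["lake_temp"] = by_year["lake_temp"].rename(lambda y: y + lake_lag)

    if seldiff is None:
        sd_cols = [c for c in by_year.columns if c.startswith("seldiff_")]
        if sd_cols:
            seldiff = by_year[sd_cols].mean(axis=1)
    if seldiff is not None:
        seldiff = seldiff.copy()
        seldiff.index = seldiff.index.astype(int)
        cols["sel_diff_lag4"] = seldiff.rename(lambda y: y + 4)
        cols["sel_diff_lag5"] = seldiff.rename(lambda y: y + 5)
        cols["sel_diff_lag45mean"] = (cols["sel_diff_lag4"] + cols["sel_diff_lag5"]) / 2.0

    frame = pd.DataFrame({"anomaly": resp})
    for name, series in cols.items():
        frame[name] = series
    frame = frame.dropna()
    frame.index.name = "year"
    if frame.empty:
        raise ValueError("no years with complete response and predictors")

    continuous = [c for c in frame.columns if c != "anomaly"]
    frame, scalers = _standardize(frame, continuous)
    frame["regime"] = (frame.index >= split).astype(int)

    quad = cfg.get("quadratic", continuous)
    for c in quad:
        if c in continuous:
            frame[c + "_z2"] = frame[c + "_z"] ** 2
    for sst in ("sst_winter_aleutians", "sst_summer_bering_lag1"):
        if sst in continuous:
            frame[f"regime_x_{sst}_z"] = frame["regime"] * frame[sst + "_z"]
    return PredictorTable(frame=frame, scalers=scalers)


def screen_collinearity(
    predictors: PredictorTable | pd.DataFrame,
    threshold: float = 0.5,
    terms: list[str] | None = None,
) -> list[frozenset]:
    """Pairwise exclusion constraints among linear predictors.

    Any two predictors whose Pearson correlation exceeds ``threshold`` in
    absolute value may not enter the same candidate model.  Returns the
    list of mutually exclusive pairs (as frozensets of ``_z`` column
    names).
    """
    frame = predictors.frame if isinstance(predictors, PredictorTable) else predictors
    if terms is None:
        terms = [c for c in frame.columns if c.endswith("_z") and not c.startswith("regime_x_")]
    corr = frame[terms].corr()
    out = []
    for i, a in enumerate(terms):
        for b in terms[i + 1:]:
            if abs(corr.loc[a, b]) > threshold:
                out.append(frozenset((a, b)))
    return out


def choose_competitor(
    predictors: PredictorTable | pd.DataFrame,
    candidates: tuple[str, str] = ("pink_lag1_z", "chum_lag1_z"),
    response: str = "anomaly",
) -> str:
    """Pick the competitor-abundance predictor with higher univariate R^2.

    Pink and chum abundances in the North Pacific are strongly collinear;
    only one family enters the candidate set — the one whose univariate
    regression explains more response variance.
    """
    frame = predictors.frame if isinstance(predictors, PredictorTable) else predictors
    best, best_r2 = None, -np.inf
    y = frame[response].to_numpy(dtype=float)
    y = y - y.mean()
    for cand in candidates:
        x = frame[cand].to_numpy(dtype=float)
        x = x - x.mean()
        r2 = (x @ y) ** 2 / ((x @ x) * (y @ y))
        if r2 > best_r2:
            best, best_r2 = cand, float(r2)
    return best
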