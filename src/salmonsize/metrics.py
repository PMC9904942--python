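"""Weighted population summaries of a reconstructed age-length dataset.

All statistics are computed on the weighted representation (one row per
unique sampled fish with its draw count) and are exactly equal to the same
statistic on the fully expanded individual-level data.  Because the
reconstruction mirrors the true numbers of fish, river means are
intrinsically weighted by catch versus escapement abundance and bay-wide
means by the relative abundance of each river's run.

Lengths are mid-eye-to-fork millimetres throughout; no function rescales
units silently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from salmonsize.reconstruct import ReconstructedPopulation

__all__ = [
    "mean_size",
    "long_term_age_means",
    "size_at_age_anomalies",
    "annual_size_at_age",
    "mean_ages",
    "cv_size_at_age",
    "selection_differentials",
    "selection_differential",
    "age_group_correlations",
]

_BASIS = {"brood": "brood_year", "return": "return_year"}


def _frame(recon: ReconstructedPopulation | pd.DataFrame) -> pd.DataFrame:
    return recon.data if isinstance(recon, ReconstructedPopulation) else recon


def _scoped(df: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "baywide":
        return df
    out = df[df["river"] == scope]
    if out.empty:
        raise ValueError(f"no reconstructed fish for scope {scope!r}")
    return out


def _year_col(year_basis: str) -> str:
    try:
        return _BASIS[year_basis]
    except KeyError:
        raise ValueError(f"year_basis must be 'brood' or 'return', got {year_basis!r}") from None


def _wmean(g: pd.DataFrame, col: str = "length_mm") -> float:
    w = g["weight"].to_numpy(dtype=float)
    return float(np.average(g[col].to_numpy(dtype=float), weights=w))


def mean_size(
    recon: ReconstructedPopulation | pd.DataFrame,
    scope: str = "baywide",
    year_basis: str = "brood",
) -> pd.Series:
    """Annual mean body length (mm) of the total return for a scope.

    The mean runs over all fish across age groups (and rivers, for the
    bay-wide scope) assigned to each year on the requested basis.
    """
    df = _scoped(_frame(recon), scope)
    ycol = _year_col(year_basis)
    out = df.groupby(ycol).apply(_wmean, include_groups=False)
    out.name = "mean_length_mm"
    out.index.name = "year"
    return out


def long_term_age_means(
    recon: ReconstructedPopulation | pd.DataFrame, scope: str = "baywide"
) -> pd.Series:
    """Long-term mean length per age group (per river, or across rivers).

    For a river scope the reference is the mean over all years of that
    river's fish in each age group; bay-wide it pools rivers.
    """
    df = _scoped(_frame(recon), scope)
    out = df.groupby("age_code").apply(_wmean, include_groups=False)
    out.name = "long_term_mean_mm"
    return out


def size_at_age_anomalies(
    recon: ReconstructedPopulation | pd.DataFrame,
    scope: str = "baywide",
    year_basis: str = "brood",
) -> pd.DataFrame:
    """Annual mean size-at-age anomaly (mm) for a scope.

    Each fish's anomaly is its length minus the long-term mean length of
    its age group — computed within its river for a river scope, across
    rivers for the bay-wide scope.  The annual value is the weighted mean
    anomaly over all fish of that year, so aggregation across age groups
    is proportional to true abundance.
    """
    df = _scoped(_frame(recon), scope).copy()
    ycol = _year_col(year_basis)
    ref = long_term_age_means(df, "baywide")  # df is already scoped
    df["anom"] = df["length_mm"] - df["age_code"].map(ref)
    grouped = df.groupby(ycol)
    out = pd.DataFrame({
        "mean_anomaly_mm": grouped.apply(_wmean, col="anom", include_groups=False),
        "n_fish": grouped["weight"].sum(),
    })
    out.index.name = "year"
    out.insert(0, "scope", scope)
    out.insert(1, "year_basis", year_basis)
    return out


def annual_size_at_age(
    recon: ReconstructedPopulation | pd.DataFrame,
    scope: str = "baywide",
    year_basis: str = "brood",
) -> pd.DataFrame:
    """Wide table of annual weighted mean length per age group (years x ages)."""
    df = _scoped(_frame(recon), scope)
    ycol = _year_col(year_basis)
    out = (
        df.groupby([ycol, "age_code"])
        .apply(_wmean, include_groups=False)
        .unstack("age_code")
    )
    out.index.name = "year"
    return out


def mean_ages(
    recon: ReconstructedPopulation | pd.DataFrame,
    scope: str = "baywide",
    year_basis: str = "brood",
) -> pd.DataFrame:
    """Annual weighted mean ocean age and mean freshwater age."""
    df = _scoped(_frame(recon), scope)
    ycol = _year_col(year_basis)
    grouped = df.groupby(ycol)
    out = pd.DataFrame({
        "mean_ocean_age": grouped.apply(_wmean, col="ocean_years", include_groups=False),
        "mean_fw_age": grouped.apply(_wmean, col="fw_years", include_groups=False),
    })
    out.index.name = "year"
    return out


def cv_size_at_age(
    recon: ReconstructedPopulation | pd.DataFrame,
    age_group: str,
    year_basis: str = "brood",
    scope: str = "baywide",
) -> pd.Series:
    """Annual coefficient of variation of length within one age group.

    Uses the weighted *population* standard deviation: the weights are
    population counts, not a sample, so no n-1 correction applies.
    """
    df = _scoped(_frame(recon), scope)
    df = df[df["age_code"] == age_group]
    if df.empty:
        raise ValueError(f"no fish of age group {age_group!r} in scope {scope!r}")
    ycol = _year_col(year_basis)

    def _cv(g: pd.DataFrame) -> float:
        w = g["weight"].to_numpy(dtype=float)
        x = g["length_mm"].to_numpy(dtype=float)
        m = np.average(x, weights=w)
        var = np.average((x - m) ** 2, weights=w)
        return float(np.sqrt(var) / m)

    out = df.groupby(ycol).apply(_cv, include_groups=False)
    out.name = f"cv_{age_group}"
    out.index.name = "year"
    return out


def selection_differentials(
    recon: ReconstructedPopulation | pd.DataFrame,
    scope: str = "baywide",
) -> pd.Series:
    """Fishery selection differential per return year (mm).

    Mean length of the escapement minus mean length of the total run
    (catch + escapement): the mean trait value after versus before
    selection.  Negative when the fishery removes large fish.
    """
    df = _scoped(_frame(recon), scope)
    run = mean_size(df, "baywide", "return")  # already scoped
    esc = df[df["source"] == "escapement"]
    if esc.empty:
        raise ValueError(f"no escapement fish in scope {scope!r}")
    esc_mean = esc.groupby("return_year").apply(_wmean, include_groups=False)
    out = (esc_mean - run).dropna()
    out.name = "selection_differential_mm"
    out.index.name = "year"
    return out


def selection_differential(
    recon: ReconstructedPopulation | pd.DataFrame, river: str, return_year: int
) -> float:
    """Scalar selection differential for one river and return year."""
    series = selection_differentials(recon, scope=river)
    try:
        return float(series.loc[return_year])
    except KeyError:
        raise ValueError(f"no data for {river!r} in return year {return_year}") from None


def age_group_correlations(saa_wide: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson correlations of annual size-at-age among age groups.

    Takes the wide years-by-age table from :func:`annual_size_at_age`;
    years missing for one group are dropped pairwise.  Returns the
    correlation matrix and the mean off-diagonal correlation.
    """
    corr = saa_wide.corr(method="pearson", min_periods=3)
    k = corr.shape[0]
    if k < 2:
        raise ValueError("need at least two age groups to correlate")
    off = corr.to_numpy()[~np.eye(k, dtype=bool)]
    return corr, float(np.nanmean(off))
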