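"""Decomposition of mean-size change into size-at-age and age structure.

Mean body size of returning fish can change because fish of a given age
get smaller (size-at-age) or because the age mix of the return shifts
towards younger, smaller fish (age structure).  Both the annual mean size
and the annual mean size-at-age anomaly are in millimetres, so changes in
the two between an early and a late window compare directly; the residual
difference is, by definition, the age-structure contribution:

    delta_age_structure = delta_mean_size - delta_size_at_age   (exact)

The retrospective variant holds the early window fixed and rolls the late
window through the record, tracing when age structure compensated for, or
amplified, declining size-at-age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["DecompositionResult", "window_mean", "decompose", "retrospective"]


@dataclass(frozen=True)
class DecompositionResult:
    scope: str
    early: tuple[int, ...]
    late: tuple[int, ...]
    delta_mean_size_mm: float
    delta_saa_mm: float

    @property
    def delta_age_structure_mm(self) -> float:
        """Age-structure contribution; the identity residual, exact."""
        return self.delta_mean_size_mm - self.delta_saa_mm


def window_mean(series: pd.Series, window: Iterable[int]) -> float:
    """Unweighted mean of annual values over a set of years.

    Each year counts once (no abundance weighting).  Years missing from
    the series are dropped with a warning; an entirely missing window is
    an error.
    """
    window = sorted(int(y) for y in window)
    present = [y for y in window if y in series.index]
    missing = sorted(set(window) - set(present))
    if not present:
        raise ValueError(f"no data in window {window}")
    if missing:
        warnings.warn(f"window years {missing} missing from series; using {len(present)} year(s)")
    return float(series.loc[present].mean())


def _check_windows(early: Sequence[int], late: Sequence[int]) -> None:
    overlap = set(early) & set(late)
    if overlap:
        raise ValueError(f"early and late windows overlap in years {sorted(overlap)}")


def decompose(
    mean_size_series: pd.Series,
    anomaly_series: pd.Series,
    early: Iterable[int],
    late: Iterable[int],
    scope: str = "baywide",
) -> DecompositionResult:
    """Total size change between two windows, partitioned.

    ``mean_size_series`` and ``anomaly_series`` must be annual series on
    the same scope and year basis (conventionally brood years, which are
    unaffected by recruitment variation).  Returns late-minus-early
    changes in mean size and in size-at-age; the age-structure share is
    their difference.
    """
    early = tuple(sorted(int(y) for y in early))
    late = tuple(sorted(int(y) for y in late))
    _check_windows(early, late)
    d_mean = window_mean(mean_size_series, late) - window_mean(mean_size_series, early)
    d_saa = window_mean(anomaly_series, late) - window_mean(anomaly_series, early)
    return DecompositionResult(
        scope=scope, early=early, late=late,
        delta_mean_size_mm=d_mean, delta_saa_mm=d_saa,
    )


def retrospective(
    mean_size_series: pd.Series,
    anomaly_series: pd.Series,
    base_window: Iterable[int] | None = None,
    window: int = 5,
    step: int = 1,
    scope: str = "baywide",
) -> pd.DataFrame:
    """Rolling decomposition against a fixed early baseline.

    The base window defaults to the first ``window`` years of the record.
    For every end year from the end of the base window onward (in steps of
    ``step``), the trailing ``window``-year period ending there is compared
    to the baseline.  The first row compares the baseline to itself (all
    deltas zero) and the last row equals the single early-vs-late
    decomposition over the full record.
    """
    years = sorted(set(mean_size_series.index) & set(anomaly_series.index))
    if not years:
        raise ValueError("series share no years")
    if base_window is None:
        base_window = years[:window]
    base = tuple(sorted(int(y) for y in base_window))

    rows = []
    for end in range(base[-1], years[-1] + 1, step):
        late = [y for y in years if end - window < y <= end]
        d_mean = window_mean(mean_size_series, late) - window_mean(mean_size_series, base)
        d_saa = window_mean(anomaly_series, late) - window_mean(anomaly_series, base)
        rows.append({
            "scope": scope,
            "end_year": end,
            "delta_mean_size_mm": d_mean,
            "delta_saa_mm": d_saa,
            "delta_age_structure_mm": d_mean - d_saa,
        })
    return pd.DataFrame(rows).set_index("end_year")
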