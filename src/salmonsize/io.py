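"""Readers/writers for the tabular inputs of the analysis.

Three CSV families are handled, all UTF-8 with a header row and ``.``
decimals:

* age-length (AL) sample tables: one measured fish per row;
* brood tables: counts of returning fish by river, brood year and age
  group, split into catch and escapement;
* covariate tables: one row per calendar year with monthly regional sea
  surface temperatures, lake temperature and salmon abundances.

Validation is total: a returned table never contains a record violating a
declared invariant.  Errors name the offending rows (1-based, excluding the
header) so that agency files can be fixed in place.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from salmonsize.ages import AgeParseError, parse_age_code

log = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ValidationError",
    "read_al_samples",
    "read_brood_table",
    "read_covariates",
    "write_table",
    "load_config",
    "DEFAULT_CONFIG",
    "SST_REGIONS",
]

#: SST averaging regions (lat/lon boxes documented for provenance; the
#: package consumes pre-averaged monthly series keyed by these tokens).
SST_REGIONS: dict[str, str] = {
    "bristol_bay": "56.2-60N 157.5-163.1W",
    "bering_sea": "54.3-60N 165-180W",
    "gulf_of_alaska": "46.7-52.4N 157.5-172.5W",
    "aleutians": "50.5-58.1N 159.4-180W",
}

#: Commercial fishing districts for the seven river systems analysed.
DEFAULT_RIVER_DISTRICTS: dict[str, str] = {
    "igushik": "nushagak",
    "wood": "nushagak",
    "nushagak": "nushagak",
    "kvichak": "naknek_kvichak",
    "naknek": "naknek_kvichak",
    "egegik": "egegik",
    "ugashik": "ugashik",
}

DEFAULT_CONFIG: dict = {
    "year_range": [1960, 2020],
    "length_range_mm": [100, 1000],
    "river_districts": dict(DEFAULT_RIVER_DISTRICTS),
    "sst_regions": dict(SST_REGIONS),
    "window_years": 5,
    "regime_split_year": 1989,  # return years >= this are the post-1988/89 regime
}

AL_COLUMNS = ["river", "return_year", "age_code", "length_mm", "source"]
AL_OPTIONAL = ["mass_g", "district"]
BROOD_COLUMNS = ["river", "brood_year", "age_code", "escapement_count", "catch_count"]


class SchemaError(ValueError):
    """Header does not match the expected schema."""


class ValidationError(ValueError):
    """One or more rows violate a declared invariant; rows are listed."""

    def __init__(self, message: str, rows: Iterable[int] = ()):
        self.rows = sorted(set(int(r) for r in rows))
        if self.rows:
            shown = ", ".join(map(str, self.rows[:20]))
            more = "" if len(self.rows) <= 20 else f" (+{len(self.rows) - 20} more)"
            message = f"{message} [rows: {shown}{more}]"
        super().__init__(message)


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _bad_age_rows(codes: pd.Series) -> list[int]:
    bad = []
    for idx, code in codes.items():
        try:
            parse_age_code(str(code))
        except AgeParseError:
            bad.append(idx + 1)
    return bad


def read_al_samples(path: str | Path, schema_cfg: Mapping | None = None) -> pd.DataFrame:
    """Read and validate an age-length sample table.

    Parameters
    ----------
    path
        CSV with columns ``river, return_year, age_code, length_mm, source``
        and optional ``mass_g, district``.
    schema_cfg
        Optional mapping with ``column_map`` (file column -> canonical
        name), ``year_range`` and ``length_range_mm`` overrides.

    Returns
    -------
    DataFrame with canonical columns and dtypes; the index is the 1-based
    data row number of the source file.
    """
    cfg = dict(DEFAULT_CONFIG)
    if schema_cfg:
        cfg.update(schema_cfg)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map := (schema_cfg or {}).get("column_map"):
        df = df.rename(columns=dict(column_map))
    _require_columns(df, AL_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: AL sample file contains a header but no rows")
        for col in AL_OPTIONAL:
            if col not in df.columns:
                df[col] = pd.Series(dtype=float if col == "mass_g" else object)
        return df

    df = df.copy()
    df.index = pd.RangeIndex(1, len(df) + 1, name="row")
    df["river"] = df["river"].astype(str).str.strip().str.lower()
    df["source"] = df["source"].astype(str).str.strip().str.lower()
    df["age_code"] = df["age_code"].astype(str).str.strip()

    bad_source = df.index[~df["source"].isin(["catch", "escapement"])]
    if len(bad_source):
        raise ValidationError("source must be 'catch' or 'escapement'", bad_source)

    bad_age = _bad_age_rows(df["age_code"].reset_index(drop=True))
    if bad_age:
        raise ValidationError("unparseable age_code values", bad_age)

    lengths = pd.to_numeric(df["length_mm"], errors="coerce")
    lo, hi = cfg["length_range_mm"]
    bad_len = df.index[lengths.isna() | (lengths <= lo) | (lengths >= hi)]
    if len(bad_len):
        raise ValidationError(f"length_mm must be numeric in ({lo}, {hi}) mm", bad_len)
    df["length_mm"] = lengths.astype(float)

    years = pd.to_numeric(df["return_year"], errors="coerce")
    y0, y1 = cfg["year_range"]
    bad_year = df.index[years.isna() | (years < y0) | (years > y1)]
    if len(bad_year):
        raise ValidationError(f"return_year must lie in [{y0}, {y1}]", bad_year)
    df["return_year"] = years.astype(int)

    if "mass_g" in df.columns:
        mass = pd.to_numeric(df["mass_g"], errors="coerce")
        bad_mass = df.index[df["mass_g"].notna() & (mass.isna() | (mass <= 0))]
        if len(bad_mass):
            raise ValidationError("mass_g, when present, must be a positive number", bad_mass)
        df["mass_g"] = mass
    else:
        df["mass_g"] = pd.NA
    if "district" in df.columns:
        df["district"] = df["district"].astype("string").str.strip().str.lower()
    else:
        df["district"] = pd.NA
    return df


def read_brood_table(path: str | Path) -> pd.DataFrame:
    """Read a brood table: returns by river, brood year and age group.

    Counts may be non-integer (they originate from run reconstructions) and
    are stored as reals; rounding happens only at resampling time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    _require_columns(df, BROOD_COLUMNS, path)
    if df.empty:
        warnings.warn(f"{path}: brood table contains a header but no rows")
        return df
    df = df.copy()
    df.index = pd.RangeIndex(1, len(df) + 1, name="row")
    df["river"] = df["river"].astype(str).str.strip().str.lower()
    df["age_code"] = df["age_code"].astype(str).str.strip()

    bad_age = _bad_age_rows(df["age_code"].reset_index(drop=True))
    if bad_age:
        raise ValidationError("unparseable age_code values", bad_age)
    df["brood_year"] = pd.to_numeric(df["brood_year"], errors="raise").astype(int)

    for col in ("escapement_count", "catch_count"):
        counts = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[counts.isna() | (counts < 0)]
        if len(bad):
            raise ValidationError(f"{col} must be a nonnegative number", bad)
        df[col] = counts.astype(float)

    dup = df.duplicated(subset=["river", "brood_year", "age_code"], keep=False)
    if dup.any():
        raise ValidationError(
            "duplicate (river, brood_year, age_code) keys", df.index[dup]
        )
    df["total_count"] = df["escapement_count"] + df["catch_count"]
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read the covariate table: one row per year, contiguous span.

    Expected columns: ``year``; ``sockeye_run``, ``pink_abund``,
    ``chum_abund`` (millions of fish); ``lake_temp`` (degC); monthly SST
    columns ``sst_<region>_<mm>`` for each configured region token; optional
    per-river selection differentials ``seldiff_<river>`` (mm).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    _require_columns(df, ["year"], path)
    df = df.copy()
    df.index = pd.RangeIndex(1, len(df) + 1, name="row")
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    if df["year"].duplicated().any():
        raise ValidationError(
            "duplicate year rows", df.index[df["year"].duplicated(keep=False)]
        )
    years = df["year"].sort_values()
    full = set(range(years.iloc[0], years.iloc[-1] + 1))
    gaps = sorted(full - set(years))
    if gaps:
        raise ValidationError(f"missing years inside the span: {gaps}")
    value_cols = [c for c in df.columns if c != "year"]
    for col in value_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & vals.isna()]
        if len(bad):
            raise ValidationError(f"non-numeric value in column {col!r}", bad)
        df[col] = vals
    return df.sort_values("year").reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any validated table back to CSV (round-trip safe)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, overlaying package defaults."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg
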