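"""Reconstruction of complete age-length populations.

Agency age-length (AL) samples describe the *sizes* of returning fish but
not their *numbers*; brood tables carry the numbers (catch and escapement
by river, brood year and age group) but not sizes.  This module combines
the two: for every brood-table cell, the recorded number of fish is
resampled with replacement from the eligible AL samples — escapement fish
from river-matched escapement samples, harvested fish from district-matched
catch samples, because catch cannot be assigned to natal rivers within a
fishing district.

The result stands in for billions of individual fish but is stored as a
weighted multinomial draw over the unique sampled fish: each output row is
one sampled fish with the number of times it was drawn.  Every weighted
statistic on this representation equals the same statistic on the fully
expanded individual-level data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from salmonsize.ages import parse_age_code
from salmonsize.io import DEFAULT_RIVER_DISTRICTS

log = logging.getLogger(__name__)

__all__ = ["ReconstructedPopulation", "reconstruct", "largest_remainder_round"]

RECON_COLUMNS = [
    "river", "brood_year", "return_year", "age_code",
    "fw_years", "ocean_years", "source", "length_mm", "weight",
]


@dataclass
class ReconstructedPopulation:
    """Weighted length distributions per (river, year, age group, source).

    ``data`` has one row per unique sampled fish per cell with its draw
    count in ``weight``; both ``brood_year`` and ``return_year`` are
    first-class keys.  ``manifest`` records, per brood-table cell, the
    sample pool used (fallback level 0-2) or that the cell was dropped.
    """

    data: pd.DataFrame
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_fish(self) -> float:
        """Total reconstructed population size (sum of weights)."""
        return float(self.data["weight"].sum()) if len(self.data) else 0.0

    def filter(self, *, river: str | None = None, source: str | None = None) -> "ReconstructedPopulation":
        d = self.data
        if river is not None:
            d = d[d["river"] == river]
        if source is not None:
            d = d[d["source"] == source]
        return ReconstructedPopulation(d, self.manifest)

    def expand(self, max_rows: int = 10_000_000) -> pd.DataFrame:
        """Explode weights into individual fish rows (oracle for tests)."""
        n = int(self.data["weight"].sum())
        if n > max_rows:
            raise MemoryError(f"expansion would create {n} rows (> {max_rows})")
        return self.data.loc[self.data.index.repeat(self.data["weight"].astype(int))].reset_index(drop=True)


def largest_remainder_round(counts: np.ndarray) -> np.ndarray:
    """Round nonnegative reals to integers preserving the rounded total.

    Floors every count, then distributes the remaining units to the cells
    with the largest fractional remainders (ties broken by cell order).
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    floors = np.floor(counts).astype(np.int64)
    target = int(np.round(counts.sum()))
    short = target - int(floors.sum())
    if short <= 0:
        return floors
    remainders = counts - floors
    order = np.argsort(-remainders, kind="stable")
    floors[order[:short]] += 1
    return floors


def _pool_key_frames(al: pd.DataFrame, river_district_map: Mapping[str, str]):
    """Index AL samples into lookup pools of length arrays."""
    al = al.copy()
    district = al["district"].astype(object) if "district" in al.columns else pd.Series(pd.NA, index=al.index)
    # catch samples without an explicit district inherit their river's district
    inferred = al["river"].map(lambda r: river_district_map.get(r, r))
    al["district"] = district.where(district.notna(), inferred)

    esc = {}
    catch = {}
    river_any = {}
    for (river, year, age), grp in al.groupby(["river", "return_year", "age_code"], sort=True):
        river_any[(river, int(year), age)] = grp["length_mm"].to_numpy()
        e = grp[grp["source"] == "escapement"]
        if len(e):
            esc[(river, int(year), age)] = e["length_mm"].to_numpy()
    catch_rows = al[al["source"] == "catch"]
    for (dist, year, age), grp in catch_rows.groupby(["district", "return_year", "age_code"], sort=True):
        catch[(dist, int(year), age)] = grp["length_mm"].to_numpy()
    return esc, catch, river_any


def reconstruct(
    al: pd.DataFrame,
    brood: pd.DataFrame,
    river_district_map: Mapping[str, str] | None = None,
    seed: int = 0,
) -> ReconstructedPopulation:
    """Resample AL samples according to brood-table counts.

    For each (river, brood year, age group) cell, ``escapement_count`` fish
    are drawn with replacement from that river's escapement AL samples of
    the matching return year and age, and ``catch_count`` fish from the
    matching district catch samples.  Cells whose natural pool is empty
    fall back to (1) all samples from the river regardless of source, then
    (2) district catch samples; cells with no eligible samples at all are
    dropped and reported in the coverage manifest.

    Non-integer brood counts are rounded by largest remainder within each
    (river, brood year) so totals are conserved to +/-1 per age group.
    Fixed ``seed`` gives an identical reconstruction.
    """
    river_district_map = dict(river_district_map or DEFAULT_RIVER_DISTRICTS)
    rng = np.random.default_rng(seed)
    esc_pools, catch_pools, river_pools = _pool_key_frames(al, river_district_map)

    rows: list[tuple] = []
    manifest: list[dict] = []

    for (river, brood_year), grp in brood.groupby(["river", "brood_year"], sort=True):
        # largest-remainder rounding across the (age x source) cells of this
        # river/brood-year so the rounded total matches the brood total
        raw = np.concatenate([grp["escapement_count"].to_numpy(), grp["catch_count"].to_numpy()])
        rounded = largest_remainder_round(raw)
        esc_counts, catch_counts = rounded[: len(grp)], rounded[len(grp):]

        for i, (_, cell) in enumerate(grp.iterrows()):
            age_code = cell["age_code"]
            age = parse_age_code(age_code)
            return_year = int(brood_year) + age.total_age
            district = river_district_map.get(river, river)
            for source, n in (("escapement", int(esc_counts[i])), ("catch", int(catch_counts[i]))):
                if n == 0:
                    continue
                if source == "escapement":
                    native = esc_pools.get((river, return_year, age_code))
                else:
                    native = catch_pools.get((district, return_year, age_code))
                ladder = [
                    (0, native),
                    (1, river_pools.get((river, return_year, age_code))),
                    (2, catch_pools.get((district, return_year, age_code))),
                ]
                pool, level = None, None
                for lvl, cand in ladder:
                    if cand is not None and len(cand):
                        pool, level = cand, lvl
                        break
                manifest.append({
                    "river": river, "brood_year": int(brood_year), "return_year": return_year,
                    "age_code": age_code, "source": source, "count": n,
                    "fallback_level": -1 if pool is None else level,
                    "status": "dropped" if pool is None else "ok",
                    "pool_size": 0 if pool is None else len(pool),
                })
                if pool is None:
                    log.warning(
                        "dropping cell (%s, brood %s, age %s, %s): %d fish, no eligible AL samples",
                        river, brood_year, age_code, source, n,
                    )
                    continue
                draws = rng.multinomial(n, np.full(len(pool), 1.0 / len(pool)))
                hit = draws > 0
                for length, w in zip(pool[hit], draws[hit]):
                    rows.append((river, int(brood_year), return_year, age_code,
                                 age.fw_years, age.ocean_years, source, float(length), int(w)))

    data = pd.DataFrame(rows, columns=RECON_COLUMNS)
    manifest_df = pd.DataFrame(manifest)
    return ReconstructedPopulation(data=data, manifest=manifest_df)
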