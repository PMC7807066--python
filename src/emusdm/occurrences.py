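"""Occurrence-record cleaning and spatial thinning.

Replicates the standard hygiene applied to opportunistic atlas sightings
before niche modelling: drop records with coarse coordinates (> 5 km
uncertainty), recorded absences, fossils, records outside the predictor
time frame (1970-present) or without a year, exact duplicates, records near
city centres, records inside user-supplied exclusion polygons, and spatial
outliers (> 30 km from every other record).  Surviving presences are thinned
so no two are closer than a minimum separation (default 30 km), reducing
pseudo-replication of wide-ranging individuals.

Occurrence sets are plain pandas DataFrames with the columns
``lon, lat, year, coord_uncertainty_m, is_fossil, is_absence_record, source``
(extra columns pass through untouched).  Coordinates are kilometres on
planar grids and degrees on geographic ones; all distance rules honour the
``geographic`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distances import nearest_neighbor_km, pairwise_dist_km

__all__ = ["CleaningRules", "CleaningReport", "clean", "thin", "remove_outliers"]


@dataclass(frozen=True)
class CleaningRules:
    max_uncertainty_km: float = 5.0
    min_year: int = 1970
    drop_fossils: bool = True
    drop_absences: bool = True
    require_year: bool = True
    drop_missing_uncertainty: bool = False
    city_exclusion_km: float = 10.0
    outlier_radius_km: float = 30.0
    dedup_decimals: int = 6
    excluded_region_masks: tuple = ()  # shapely geometries

    def __post_init__(self) -> None:
        for name in ("max_uncertainty_km", "city_exclusion_km", "outlier_radius_km"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CleaningReport:
    n_input: int
    n_retained: int
    removed_by_rule: dict[str, int] = field(default_factory=dict)
    all_removed: bool = False

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_by_rule": dict(self.removed_by_rule),
            "all_removed": self.all_removed,
        }


def _coords(df: pd.DataFrame) -> np.ndarray:
    return df[["lon", "lat"]].to_numpy(dtype=float)


def clean(
    records: pd.DataFrame,
    rules: CleaningRules = CleaningRules(),
    city_points: np.ndarray | Sequence | None = None,
    geographic: bool = False,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply every cleaning rule; return survivors and per-rule removal counts.

    A record violating several rules is counted once under each rule it
    violates but removed only once.  Removing all records is flagged in the
    report, not fatal.  The operation is idempotent and (up to the canonical
    duplicate choice) permutation-invariant.
    """
    if len(records) == 0:
        raise ValueError("no records to clean")
    df = records.reset_index(drop=True)
    n = len(df)
    violate: dict[str, np.ndarray] = {}

    unc = df["coord_uncertainty_m"].to_numpy(dtype=float)
    too_coarse = unc > rules.max_uncertainty_km * 1000.0
    if rules.drop_missing_uncertainty:
        too_coarse = too_coarse | np.isnan(unc)
    else:
        too_coarse = np.where(np.isnan(unc), False, too_coarse)
    violate["uncertainty"] = too_coarse

    if rules.drop_absences:
        violate["absence"] = df["is_absence_record"].to_numpy(dtype=bool)
    if rules.drop_fossils:
        violate["fossil"] = df["is_fossil"].to_numpy(dtype=bool)

    year = df["year"].to_numpy(dtype=float)
    if rules.require_year:
        violate["missing_year"] = np.isnan(year)
    violate["early_year"] = np.where(np.isnan(year), False, year < rules.min_year)

    flagged = np.zeros(n, dtype=bool)
    for mask in violate.values():
        flagged |= mask

    # Duplicates among records passing the flag rules, using rounded
    # coordinates; the canonical survivor is the first in a full-column sort
    # so the result does not depend on input order.
    keep_candidates = ~flagged
    dup = np.zeros(n, dtype=bool)
    cand_idx = np.flatnonzero(keep_candidates)
    if len(cand_idx) > 1:
        sub = df.loc[cand_idx].copy()
        sub["_rlon"] = sub["lon"].round(rules.dedup_decimals)
        sub["_rlat"] = sub["lat"].round(rules.dedup_decimals)
        order_cols = ["_rlon", "_rlat", "year", "coord_uncertainty_m", "source"]
        sub = sub.sort_values(order_cols, kind="mergesort", na_position="last")
        dup_mask = sub.duplicated(subset=["_rlon", "_rlat"], keep="first")
        dup[sub.index[dup_mask.to_numpy()]] = True
    violate["duplicate"] = dup
    flagged |= dup

    # City exclusion on the remaining records.
    city = np.zeros(n, dtype=bool)
    if city_points is not None and len(np.atleast_2d(city_points)) > 0:
        rem = np.flatnonzero(~flagged)
        if len(rem) > 0:
            d = pairwise_dist_km(_coords(df.loc[rem]), np.atleast_2d(city_points), geographic)
            city[rem] = d.min(axis=1) < rules.city_exclusion_km
    violate["city"] = city
    flagged |= city

    # Exclusion polygons (shapely geometries in the same coordinate system).
    region = np.zeros(n, dtype=bool)
    if rules.excluded_region_masks:
        from shapely.geometry import Point

        rem = np.flatnonzero(~flagged)
        for i in rem:
            p = Point(df.at[i, "lon"], df.at[i, "lat"])
            if any(geom.contains(p) for geom in rules.excluded_region_masks):
                region[i] = True
    violate["region"] = region
    flagged |= region

    # Spatial outliers among the otherwise-clean records: nearest neighbour
    # farther than the radius.  An outlier by definition has no neighbour
    # within the radius, so removing outliers never orphans a kept record
    # and the pass is idempotent.
    outlier = np.zeros(n, dtype=bool)
    rem = np.flatnonzero(~flagged)
    if len(rem) > 1:
        nn = nearest_neighbor_km(_coords(df.loc[rem]), geographic)
        outlier[rem] = nn > rules.outlier_radius_km
    violate["outlier"] = outlier
    flagged |= outlier

    kept = df.loc[~flagged].reset_index(drop=True)
    report = CleaningReport(
        n_input=n,
        n_retained=len(kept),
        removed_by_rule={k: int(v.sum()) for k, v in violate.items()},
        all_removed=len(kept) == 0,
    )
    return kept, report


def thin(
    points: pd.DataFrame,
    min_dist_km: float,
    seed: int,
    geographic: bool = False,
) -> pd.DataFrame:
    """Greedy spatial thinning: seeded random order, accept-if-far-enough.

    Output is a subset of the input whose pairwise distances are all
    >= ``min_dist_km``; fully determined by (input, seed).
    """
    if not min_dist_km > 0:
        raise ValueError("min_dist_km must be positive")
    df = points.reset_index(drop=True)
    if len(df) <= 1:
        return df
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    xy = _coords(df)
    accepted: list[int] = []
    for i in order:
        if not accepted:
            accepted.append(i)
            continue
        d = pairwise_dist_km(xy[i : i + 1], xy[accepted], geographic)[0]
        if d.min() >= min_dist_km:
            accepted.append(i)
    accepted_sorted = sorted(accepted)
    return df.loc[accepted_sorted].reset_index(drop=True)


def remove_outliers(
    points: pd.DataFrame,
    radius_km: float,
    geographic: bool = False,
) -> pd.DataFrame:
    """Drop every point whose nearest neighbour is farther than ``radius_km``."""
    if len(points) < 2:
        raise ValueError("outlier removal needs at least 2 points")
    df = points.reset_index(drop=True)
    nn = nearest_neighbor_km(_coords(df), geographic)
    return df.loc[nn <= radius_km].reset_index(drop=True)
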