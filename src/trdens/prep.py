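"""Tract preparation: classification, filtering, and geometry rules.

Implements the analysis-frame construction rules: dichotomisation of
sociodemographic percentages into high/low indicators, the NCHS county
level to urban/suburban/rural mapping, the minimum-population and
missing-poverty exclusions (applied tract-wise across both years to keep
the paired design intact), point-in-tract retailer tallies, and the
"contained within or >= 50% overlap" licensing assignment for city
polygons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

__all__ = [
    "classify_prevalence",
    "classify_rurality",
    "prepare_table",
    "filter_tracts",
    "count_points_in_tracts",
    "assign_licensing",
    "MIN_POPULATION",
    "CUTOFF_AA",
    "CUTOFF_HISPANIC",
    "CUTOFF_UNDER18",
    "CUTOFF_POVERTY",
]

MIN_POPULATION = 500
CUTOFF_AA = 15.0
CUTOFF_HISPANIC = 15.0
CUTOFF_UNDER18 = 25.0
CUTOFF_POVERTY = 15.4  # state poverty level at baseline; strict ">"

_NCHS_MAP = {1: "urban", 2: "suburban", 3: "suburban", 4: "rural", 5: "rural", 6: "rural"}

# exclusion reasons in priority order
REASON_ZERO_POP = "zero_population"
REASON_MIN_POP = "population_below_minimum"
REASON_MISSING_POVERTY = "missing_poverty"


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def classify_prevalence(pct_aa, pct_hisp, pct_under18, pct_poverty):
    """Dichotomise tract percentages into high/low indicators.

    High African American / Hispanic prevalence at >= 15%, high prevalence
    of children (under 18) at >= 25%, and high poverty strictly above
    15.4% (the baseline state poverty level; the poverty comparator is
    deliberately strict while the others are inclusive).  A missing poverty
    percentage returns ``None`` for the poverty flag; such rows are removed
    by :func:`filter_tracts`.
    """
    for name, val in (("pct_aa", pct_aa), ("pct_hisp", pct_hisp), ("pct_under18", pct_under18)):
        if _is_missing(val) or not 0 <= val <= 100:
            raise ValueError(f"{name}={val!r} outside [0, 100]")
    if not _is_missing(pct_poverty) and not 0 <= pct_poverty <= 100:
        raise ValueError(f"pct_poverty={pct_poverty!r} outside [0, 100]")
    high_poverty = None if _is_missing(pct_poverty) else bool(pct_poverty > CUTOFF_POVERTY)
    return (
        bool(pct_aa >= CUTOFF_AA),
        bool(pct_hisp >= CUTOFF_HISPANIC),
        bool(pct_under18 >= CUTOFF_UNDER18),
        high_poverty,
    )


def classify_rurality(nchs_level: int) -> str:
    """Map the 6-level NCHS county classification to urban/suburban/rural.

    Level 1 is urban, levels 2-3 suburban, levels 4-6 rural.
    """
    try:
        level = int(nchs_level)
    except (TypeError, ValueError):
        raise ValueError(f"NCHS level must be an integer 1-6, got {nchs_level!r}") from None
    if level not in _NCHS_MAP:
        raise ValueError(f"NCHS level must be in 1..6, got {level}")
    return _NCHS_MAP[level]


def prepare_table(raw: pd.DataFrame) -> pd.DataFrame:
    """Add classification flags and rurality to a raw tract-year table.

    Expects the percentage columns (pct_african_american, pct_hispanic,
    pct_under18, pct_poverty) and nchs_level; recomputes high_aa,
    high_hisp, high_children, high_poverty and rurality from them.  The
    poverty flag is left as a nullable boolean where the percentage is
    missing.
    """
    required = ["pct_african_american", "pct_hispanic", "pct_under18", "pct_poverty", "nchs_level"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"raw table missing columns: {missing}")
    for col in required[:3]:
        bad = raw[(raw[col] < 0) | (raw[col] > 100) | raw[col].isna()]
        if len(bad):
            raise ValueError(f"{col} outside [0, 100] (or missing) in rows {bad.index.tolist()[:5]}")
    pov = raw["pct_poverty"]
    bad = raw[(pov < 0) | (pov > 100)]
    if len(bad):
        raise ValueError(f"pct_poverty outside [0, 100] in rows {bad.index.tolist()[:5]}")

    out = raw.copy()
    out["high_aa"] = out["pct_african_american"] >= CUTOFF_AA
    out["high_hisp"] = out["pct_hispanic"] >= CUTOFF_HISPANIC
    out["high_children"] = out["pct_under18"] >= CUTOFF_UNDER18
    out["high_poverty"] = pd.array(
        [None if _is_missing(v) else v > CUTOFF_POVERTY for v in pov], dtype="boolean"
    )
    out["rurality"] = out["nchs_level"].map(lambda v: classify_rurality(v))
    return out


def filter_tracts(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the analysis-frame exclusions, tract-wise across both years.

    A tract is dropped (from both years) if in either year its population
    is zero, below the 500-person minimum, or its poverty percentage is
    missing.  One reason is logged per excluded tract with priority
    zero_population > population_below_minimum > missing_poverty.  The
    operation is idempotent.

    Returns ``(kept_table, exclusion_log)`` where the log has columns
    ``tract_id`` and ``reason``.
    """
    if len(table) == 0:
        return table.copy(), pd.DataFrame(columns=["tract_id", "reason"])

    exclusions = []
    for tract_id, grp in table.groupby("tract_id", sort=True):
        pops = grp["population"]
        pov_missing = grp["pct_poverty"].isna().any() if "pct_poverty" in grp else False
        if "high_poverty" in grp:
            pov_missing = pov_missing or grp["high_poverty"].isna().any()
        if (pops == 0).any():
            exclusions.append((tract_id, REASON_ZERO_POP))
        elif (pops < MIN_POPULATION).any():
            exclusions.append((tract_id, REASON_MIN_POP))
        elif pov_missing:
            exclusions.append((tract_id, REASON_MISSING_POVERTY))
    log = pd.DataFrame(exclusions, columns=["tract_id", "reason"])
    kept = table[~table["tract_id"].isin(log["tract_id"])].reset_index(drop=True)
    return kept, log


def _validate_polygons(polys: dict) -> None:
    for pid, poly in polys.items():
        if poly.is_empty or poly.area <= 0:
            raise ValueError(f"polygon {pid!r} has zero area")
        if not poly.is_valid:
            raise ValueError(f"polygon {pid!r} is invalid (self-intersecting?)")


def _check_no_overlap(polys: dict) -> None:
    ids = sorted(polys)
    geoms = [polys[i] for i in ids]
    tree = STRtree(geoms)
    for i, geom in enumerate(geoms):
        for j in tree.query(geom):
            if j <= i:
                continue
            inter = geom.intersection(geoms[j])
            if inter.area > 1e-12 * min(geom.area, geoms[j].area):
                raise ValueError(
                    f"tract polygons {ids[i]!r} and {ids[j]!r} overlap; "
                    "tract geometries must partition the plane"
                )


def count_points_in_tracts(points, tracts: dict) -> tuple[pd.Series, int]:
    """Tally planar points (e.g., geocoded retailers) per tract polygon.

    ``tracts`` maps tract_id to a shapely polygon; polygons must not
    overlap.  A point on a shared boundary is assigned deterministically to
    the lowest tract_id among the touching polygons.  Points covered by no
    polygon are counted and reported, never silently dropped.

    Returns ``(counts, n_unassigned)`` with counts indexed by tract_id.
    """
    _validate_polygons(tracts)
    _check_no_overlap(tracts)
    ids = sorted(tracts)
    geoms = [tracts[i] for i in ids]
    tree = STRtree(geoms)
    counts = pd.Series(0, index=pd.Index(ids, name="tract_id"), dtype=int)
    unassigned = 0
    for xy in points:
        pt = Point(xy)
        if not (np.isfinite(pt.x) and np.isfinite(pt.y)):
            raise ValueError(f"non-finite point coordinates: {xy!r}")
        hits = sorted(ids[k] for k in tree.query(pt, predicate="covered_by"))
        if hits:
            counts[hits[0]] += 1
        else:
            unassigned += 1
    return counts, unassigned


@dataclass(frozen=True)
class OverlapResult:
    licensed: bool
    fraction: float


def assign_licensing(tracts: dict, cities: dict) -> pd.Series:
    """Flag tracts covered by a licensing city polygon.

    A tract is licensed iff it is fully contained in some city polygon or
    at least 50% of its area (inclusive) intersects one.  Overlap fractions
    are area-based.
    """
    _validate_polygons(tracts)
    _validate_polygons(cities)
    ids = sorted(tracts)
    city_geoms = list(cities.values())
    tree = STRtree(city_geoms) if city_geoms else None
    flags = {}
    for tid in ids:
        tract = tracts[tid]
        licensed = False
        if tree is not None:
            for k in tree.query(tract, predicate="intersects"):
                city = city_geoms[k]
                if tract.within(city):
                    licensed = True
                    break
                frac = tract.intersection(city).area / tract.area
                # inclusive at exactly one half, robust to float round-off
                if frac >= 0.5 - 1e-12:
                    licensed = True
                    break
        flags[tid] = licensed
    return pd.Series(flags, name="licensing").rename_axis("tract_id")
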