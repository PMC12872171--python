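"""Descriptive disparity metrics for tract-level retailer density.

Tobacco retailer density (TRD) is retailers per 1000 residents.  This
module computes TRD, group medians and prevalences by year, percent
changes, the disparity / equitable-decline comparisons between a divested
group and its reference, and the tract-level change summary (shares of
tracts whose TRD rose, fell, or held, with conditional mean magnitudes and
the aggregate statewide change).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_trd",
    "group_median_trd",
    "percent_change",
    "disparity_flags",
    "change_summary",
    "describe_all",
    "GROUPINGS",
    "ChangeSummary",
    "DisparityFlags",
]

# standard grouping variables and the divested level of each
GROUPINGS = {
    "high_aa": True,
    "high_hisp": True,
    "high_children": True,
    "high_poverty": True,
    "rurality": "rural",
    "licensing": True,
}


def compute_trd(retailer_count, population):
    """Retailers per 1000 residents: ``1000 * count / population``.

    Accepts scalars or aligned arrays; population must be strictly
    positive (the filtering stage guarantees this).
    """
    count = np.asarray(retailer_count, dtype=float)
    pop = np.asarray(population, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population must be positive to compute TRD")
    out = 1000.0 * count / pop
    return float(out) if out.ndim == 0 else out


def _with_trd(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    out["trd"] = compute_trd(out["retailer_count"], out["population"])
    return out


def group_median_trd(table: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Median TRD and tract prevalence by level of ``grouping``, per year.

    The median is the midpoint of the two central order statistics for an
    even number of tracts.  Prevalence is the percent of tracts in each
    level within the year, summing to 100.
    """
    if grouping not in table.columns:
        raise ValueError(f"unknown grouping variable {grouping!r}")
    if len(table) == 0:
        raise ValueError("empty table")
    df = _with_trd(table)
    rows = []
    for year, block in df.groupby("year"):
        n_year = len(block)
        for level, grp in block.groupby(grouping, sort=True):
            rows.append(
                {
                    "grouping": grouping,
                    "level": level,
                    "year": year,
                    "prevalence_pct": 100.0 * len(grp) / n_year,
                    "median_trd": float(np.median(grp["trd"])),
                }
            )
    return pd.DataFrame(rows)


def percent_change(old_value: float, new_value: float) -> float:
    """Percent change ``100 * (new - old) / old``.

    Undefined for ``old_value == 0``: returns NaN (the "not applicable"
    convention for change cells with no valid base).  Carried unrounded;
    round only for display.
    """
    if old_value == 0 or _isnan(old_value) or _isnan(new_value):
        return math.nan
    return 100.0 * (new_value - old_value) / old_value


def _isnan(x) -> bool:
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return False


@dataclass(frozen=True)
class DisparityFlags:
    disparity_by_year: dict
    equitable_decline: bool
    pct_change_divested: float
    pct_change_reference: float


def disparity_flags(summary: pd.DataFrame, divested_level) -> DisparityFlags:
    """Disparity and equitable-decline indicators for a two-level grouping.

    A year shows a disparity when the divested level's median TRD strictly
    exceeds the reference level's.  The decline is equitable when the
    divested level's percent change in median TRD is strictly more negative
    (a greater decline) than the reference's.  Groupings with more than two
    levels (rurality) are handled by explicit pairwise calls.
    """
    levels = sorted(summary["level"].unique(), key=str)
    if len(levels) != 2:
        raise ValueError(f"disparity_flags needs exactly two levels, got {levels}")
    if divested_level not in levels:
        raise ValueError(f"divested level {divested_level!r} not among {levels}")
    reference_level = next(l for l in levels if l != divested_level)

    med = summary.pivot(index="year", columns="level", values="median_trd")
    disparity = {
        int(year): bool(med.loc[year, divested_level] > med.loc[year, reference_level])
        for year in med.index
    }
    years = sorted(med.index)
    pc_div = percent_change(med.loc[years[0], divested_level], med.loc[years[-1], divested_level])
    pc_ref = percent_change(med.loc[years[0], reference_level], med.loc[years[-1], reference_level])
    equitable = bool(pc_div < pc_ref) if not (_isnan(pc_div) or _isnan(pc_ref)) else False
    return DisparityFlags(disparity, equitable, pc_div, pc_ref)


@dataclass(frozen=True)
class ChangeSummary:
    fraction_increased: float
    fraction_decreased: float
    fraction_unchanged: float
    mean_increase: float  # NaN when no tract increased
    mean_decrease: float  # NaN when no tract decreased
    overall_pct_change: float


def change_summary(table: pd.DataFrame) -> ChangeSummary:
    """Tract-level TRD change between the two years.

    Fractions of tracts whose TRD increased / decreased / held; conditional
    mean magnitude of increases and decreases (retailers per 1000 among
    changed tracts); and the aggregate statewide percent change, computed
    from summed counts over summed populations per year (a ratio of
    aggregates, not the mean of tract-level changes).
    """
    df = _with_trd(table)
    years = sorted(df["year"].unique())
    if len(years) != 2:
        raise ValueError(f"change_summary needs exactly two years, got {years}")
    wide = df.pivot(index="tract_id", columns="year", values="trd")
    if wide.isna().any().any():
        raise ValueError("every tract must appear in both years")
    delta = wide[years[1]] - wide[years[0]]
    n = len(delta)
    inc = delta[delta > 0]
    dec = delta[delta < 0]
    agg = df.groupby("year").agg(count=("retailer_count", "sum"), pop=("population", "sum"))
    statewide = 1000.0 * agg["count"] / agg["pop"]
    return ChangeSummary(
        fraction_increased=len(inc) / n,
        fraction_decreased=len(dec) / n,
        fraction_unchanged=1.0 - len(inc) / n - len(dec) / n,
        mean_increase=float(inc.mean()) if len(inc) else math.nan,
        mean_decrease=float(-dec.mean()) if len(dec) else math.nan,
        overall_pct_change=percent_change(statewide[years[0]], statewide[years[1]]),
    )


def describe_all(table: pd.DataFrame) -> pd.DataFrame:
    """Group summaries for every standard grouping variable.

    One row per grouping x level x year with prevalence, median TRD, and
    the percent change in median TRD across years attached to each level.
    """
    pieces = []
    for grouping in GROUPINGS:
        if grouping not in table.columns:
            continue
        summary = group_median_trd(table, grouping)
        wide = summary.pivot(index="level", columns="year", values="median_trd")
        years = sorted(table["year"].unique())
        changes = {
            level: percent_change(wide.loc[level, years[0]], wide.loc[level, years[-1]])
            for level in wide.index
        }
        summary["pct_change_median_trd"] = summary["level"].map(changes)
        pieces.append(summary)
    return pd.concat(pieces, ignore_index=True)
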