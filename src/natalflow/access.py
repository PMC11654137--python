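"""Municipal, state and national accessibility metrics.

Three measures summarise how far women go to give birth, per analysis unit
and year:

* ``F`` — the share of travelers: births occurring outside the mother's
  residence municipality, over all births of that municipality;
* ``C`` — the conditional distance: mean inter-municipal kilometres among
  travelers only (undefined when a unit has no travelers);
* ``D`` — the unconditional distance: mean kilometres over *all* births,
  counting non-travelers as 0 km.

They obey the exact identity ``D = F x C`` at every aggregation level,
because aggregation pools counts (births, travelers, traveler-km) rather
than averaging ratios. The module also provides the Gini index of
municipal conditional distances within a state, the eight-bracket
percentile classification used for cross-year mapping, and a decile-of-
municipal-size summary table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import DistanceMatrix, RegionMap, attach_distance

__all__ = [
    "muni_access",
    "aggregate",
    "gini",
    "gini_conditional_distance",
    "BracketScheme",
    "percentile_brackets",
    "decile_summary",
]

ACCESS_COLUMNS = [
    "unit",
    "year",
    "n_births",
    "n_travelers",
    "n_distance_missing",
    "traveler_km",
    "f",
    "c",
    "d",
]


def _summarise(group: pd.DataFrame) -> pd.Series:
    n_births = len(group)
    n_travelers = int(group["traveled"].sum())
    resolved = group["traveled"] & group["distance_km"].notna()
    n_resolved = int(resolved.sum())
    traveler_km = float(group.loc[resolved, "distance_km"].sum())
    f = n_travelers / n_births
    if n_travelers == 0:
        c, d = np.nan, 0.0
    elif n_resolved == 0:
        c, d = np.nan, np.nan  # travelers exist but no distance is resolvable
    else:
        c = traveler_km / n_resolved
        d = f * c
    return pd.Series(
        {
            "n_births": n_births,
            "n_travelers": n_travelers,
            "n_distance_missing": n_travelers - n_resolved,
            "traveler_km": traveler_km,
            "f": f,
            "c": c,
            "d": d,
        }
    )


def muni_access(
    births: pd.DataFrame,
    dmat: DistanceMatrix,
    year: int | None = None,
    by_year: bool = True,
) -> pd.DataFrame:
    """Per-municipality access summaries.

    One row per residence municipality (and year when ``by_year``), with
    counts, F, C and D. Travelers whose origin-destination pair is absent
    from the distance matrix are excluded from the distance statistics and
    counted in ``n_distance_missing``; they still count as travelers in F.
    Municipality-years with no births emit no row. With ``by_year=False``
    the full window is pooled and ``year`` is reported as -1.
    """
    annotated, _ = attach_distance(births, dmat)
    if year is not None:
        annotated = annotated[annotated["year"] == year]
    keys = ["residence_muni", "year"] if by_year else ["residence_muni"]
    grouped = (
        annotated.groupby(keys, sort=True)[["traveled", "distance_km"]]
        .apply(_summarise)
        .reset_index()
        .rename(columns={"residence_muni": "unit"})
    )
    if not by_year:
        grouped["year"] = -1
    for col in ("n_births", "n_travelers", "n_distance_missing"):
        grouped[col] = grouped[col].astype(int)
    return grouped[ACCESS_COLUMNS]


def aggregate(
    muni_table: pd.DataFrame,
    level: str = "state",
    region_map: RegionMap | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """Aggregate municipal summaries to state or national level.

    The default (birth-weighted) aggregation pools counts: births,
    travelers and traveler-km sum, then ``F = travelers/births``,
    ``C = traveler-km/travelers`` and ``D = F x C`` — so the identity holds
    exactly at every level and is associative (muni->state->national equals
    muni->national). ``weighted=False`` instead reports the unweighted mean
    of the municipal F, C (over municipalities where C is defined) and D,
    for which the identity need not hold.
    """
    if level not in {"state", "national"}:
        raise ValueError(f"level must be 'state' or 'national', got {level!r}")
    table = muni_table.copy()
    if level == "state":
        if region_map is None:
            raise ValueError("state aggregation requires a region_map")
        known = set(region_map.munis())
        unknown = sorted(set(table["unit"]) - known)
        if unknown:
            raise ValueError(f"municipalities missing from region map: {unknown}")
        table["agg_unit"] = table["unit"].map(
            region_map.frame.set_index("muni")["state"]
        )
    else:
        table["agg_unit"] = "BR"

    if weighted:
        pooled = (
            table.groupby(["agg_unit", "year"], sort=True)
            .agg(
                n_births=("n_births", "sum"),
                n_travelers=("n_travelers", "sum"),
                n_distance_missing=("n_distance_missing", "sum"),
                traveler_km=("traveler_km", "sum"),
            )
            .reset_index()
            .rename(columns={"agg_unit": "unit"})
        )
        n_resolved = pooled["n_travelers"] - pooled["n_distance_missing"]
        pooled["f"] = pooled["n_travelers"] / pooled["n_births"]
        pooled["c"] = np.where(
            n_resolved > 0, pooled["traveler_km"] / n_resolved.replace(0, 1), np.nan
        )
        pooled["d"] = np.where(
            pooled["n_travelers"] > 0, pooled["f"] * pooled["c"], 0.0
        )
        return pooled[ACCESS_COLUMNS]

    out = (
        table.groupby(["agg_unit", "year"], sort=True)
        .agg(
            n_births=("n_births", "sum"),
            n_travelers=("n_travelers", "sum"),
            n_distance_missing=("n_distance_missing", "sum"),
            traveler_km=("traveler_km", "sum"),
            f=("f", "mean"),
            c=("c", "mean"),  # mean over munis with C defined (NaN skipped)
            d=("d", "mean"),
        )
        .reset_index()
        .rename(columns={"agg_unit": "unit"})
    )
    return out[ACCESS_COLUMNS]


def gini(values, weights=None) -> float:
    """Gini index by mean absolute difference.

    ``G = sum_ij |x_i - x_j| / (2 n^2 xbar)`` for the unweighted case;
    the weighted form replaces counts by weights. Scale-invariant, 0 for a
    constant vector, < 1 always. NaN for fewer than 2 values or zero mean.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2 or x.mean() == 0:
        return float("nan")
    if weights is None:
        xs = np.sort(x)
        n = len(xs)
        # identity: sum_ij |xi-xj| = 2 * sum_i (2i - n + 1) x_(i)  (0-based)
        mad = 2.0 * float(((2 * np.arange(n) - n + 1) * xs).sum())
        return mad / (2.0 * n * n * xs.mean())
    w = np.asarray(weights, dtype=float)
    if len(w) != len(values):
        raise ValueError("weights length mismatch")
    keep = ~np.isnan(np.asarray(values, dtype=float))
    x, w = np.asarray(values, dtype=float)[keep], w[keep]
    wsum = w.sum()
    mean = (w * x).sum() / wsum
    if mean == 0:
        return float("nan")
    # weighted mean absolute difference, O(n^2): states hold few hundred munis
    mad = float((w[:, None] * w[None, :] * np.abs(x[:, None] - x[None, :])).sum())
    return mad / (2.0 * wsum**2 * mean)


def gini_conditional_distance(
    muni_table: pd.DataFrame,
    region_map: RegionMap,
    weighted: bool = False,
) -> pd.DataFrame:
    """Gini of municipal conditional distances within each state-year.

    Only municipalities with at least one traveler (C defined) enter; a
    state-year with fewer than 2 eligible municipalities is flagged
    undefined (NaN gini). Unweighted across municipalities by default; the
    birth-weighted variant weighs each municipality by its births.
    """
    eligible = muni_table[muni_table["n_travelers"] > 0].copy()
    eligible["state"] = eligible["unit"].map(
        region_map.frame.set_index("muni")["state"]
    )
    rows = []
    for (state, year), group in eligible.groupby(["state", "year"], sort=True):
        n_units = len(group)
        if n_units < 2:
            g = float("nan")
        elif weighted:
            g = gini(group["c"], group["n_births"])
        else:
            g = gini(group["c"])
        rows.append(
            {"unit": state, "year": year, "gini": g, "n_units": n_units,
             "defined": n_units >= 2}
        )
    return pd.DataFrame(rows, columns=["unit", "year", "gini", "n_units", "defined"])


@dataclass
class BracketScheme:
    """Eight equal-percentile brackets over a pooled value distribution.

    Cut points sit at the 12.5, 25, ..., 87.5 percentiles (linear
    interpolation between order statistics). A value's bracket is
    ``1 + #{cuts < value}``: values equal to a cut fall in the lower
    bracket, so degenerate (tied) cuts collapse and a constant distribution
    lands entirely in bracket 1.
    """

    cuts: np.ndarray  # 7 interior cut points, ascending

    def assign(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return 1 + (self.cuts[None, :] < v[:, None]).sum(axis=1)


def percentile_brackets(values) -> BracketScheme:
    """Fit the 8-bracket scheme on values pooled across all units/years.

    Pooling across years fixes one scheme so maps of different years share
    a common scale.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("no values to bracket")
    cuts = np.percentile(v, np.arange(12.5, 100.0, 12.5), method="linear")
    return BracketScheme(cuts=np.asarray(cuts))


def decile_summary(births: pd.DataFrame, dmat: DistanceMatrix) -> pd.DataFrame:
    """F and C by decile of municipal size, per year.

    Municipalities are ranked by mean annual births over the study window
    and split into 10 near-equal groups (ties broken by code for
    determinism). Within each decile x year, F and C come from pooled
    counts exactly as in :func:`aggregate`; the interval columns report the
    decile's min and max mean annual births. A decile-year with no
    travelers has C undefined (NaN).
    """
    n_years = births["year"].nunique()
    muni_size = (
        births.groupby("residence_muni").size().rename("total").reset_index()
    )
    muni_size["mean_annual"] = muni_size["total"] / n_years
    muni_size = muni_size.sort_values(["mean_annual", "residence_muni"]).reset_index(
        drop=True
    )
    n = len(muni_size)
    muni_size["decile"] = (np.arange(n) * 10) // n + 1

    table = muni_access(births, dmat, by_year=True)
    table = table.merge(
        muni_size[["residence_muni", "decile"]],
        left_on="unit",
        right_on="residence_muni",
    )
    pooled = (
        table.groupby(["decile", "year"], sort=True)
        .agg(
            n_births=("n_births", "sum"),
            n_travelers=("n_travelers", "sum"),
            n_distance_missing=("n_distance_missing", "sum"),
            traveler_km=("traveler_km", "sum"),
        )
        .reset_index()
    )
    n_resolved = pooled["n_travelers"] - pooled["n_distance_missing"]
    pooled["f"] = pooled["n_travelers"] / pooled["n_births"]
    pooled["c"] = np.where(
        n_resolved > 0, pooled["traveler_km"] / n_resolved.replace(0, 1), np.nan
    )
    intervals = muni_size.groupby("decile")["mean_annual"].agg(["min", "max"])
    pooled["births_min"] = pooled["decile"].map(intervals["min"])
    pooled["births_max"] = pooled["decile"].map(intervals["max"])
    return pooled[
        ["decile", "births_min", "births_max", "year", "n_births", "n_travelers",
         "f", "c"]
    ]
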