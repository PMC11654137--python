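"""Origin-destination flow tables and departure/arrival statistics.

Flows between residence and birth municipalities form the referral
network: typically a star, with a regional hub receiving most travelers.
Two municipality-level shares summarise it with *different denominators*:

* departure share — travelers over births to *residents* (this equals F);
* arrival share — births to non-resident mothers over births *occurring*
  in the municipality (its delivery activity).

Conflating the denominators is a classic error; arrival share answers
"what fraction of this town's deliveries are imported?", not "how many of
its residents leave?".
"""

from __future__ import annotations

import pandas as pd

from .io_model import RegionMap

__all__ = ["od_flows", "muni_flow_stats", "region_exit_share"]


def od_flows(births: pd.DataFrame, year: int | None = None) -> pd.DataFrame:
    """Count births per (origin, destination, year) pair.

    Self-pairs (non-travelers) are included and flagged ``is_self`` so per-
    origin conservation (counts sum to origin births) is checkable.
    ``share_of_origin`` divides by all births of the origin-year.
    """
    b = births if year is None else births[births["year"] == year]
    flows = (
        b.groupby(["residence_muni", "birth_muni", "year"], sort=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"residence_muni": "origin", "birth_muni": "destination"})
    )
    origin_births = flows.groupby(["origin", "year"])["count"].transform("sum")
    flows["share_of_origin"] = flows["count"] / origin_births
    flows["is_self"] = flows["origin"] == flows["destination"]
    return flows


def muni_flow_stats(flow_table: pd.DataFrame) -> pd.DataFrame:
    """Departure and arrival shares per municipality-year.

    Covers every municipality appearing as origin or destination. A
    municipality with no resident births has departure share NaN; one with
    no occurring births (pure sender) has arrival share NaN.
    """
    ft = flow_table
    resident = (
        ft.groupby(["origin", "year"])["count"].sum().rename("resident_births")
    )
    departures = (
        ft[~ft["is_self"]].groupby(["origin", "year"])["count"].sum().rename("departures")
    )
    occurring = (
        ft.groupby(["destination", "year"])["count"].sum().rename("births_occurring")
    )
    arrivals = (
        ft[~ft["is_self"]]
        .groupby(["destination", "year"])["count"]
        .sum()
        .rename("arrivals")
    )
    resident.index.names = occurring.index.names = ["muni", "year"]
    departures.index.names = arrivals.index.names = ["muni", "year"]
    stats = (
        pd.concat([resident, departures, occurring, arrivals], axis=1)
        .fillna({"departures": 0, "arrivals": 0, "resident_births": 0,
                 "births_occurring": 0})
        .astype(int)
        .reset_index()
        .sort_values(["muni", "year"])
        .reset_index(drop=True)
    )
    stats["departure_share"] = stats["departures"] / stats["resident_births"].where(
        stats["resident_births"] > 0
    )
    stats["arrival_share"] = stats["arrivals"] / stats["births_occurring"].where(
        stats["births_occurring"] > 0
    )
    return stats


def region_exit_share(
    births: pd.DataFrame, region_map: RegionMap, year: int | None = None
) -> pd.DataFrame:
    """Share of travelers who leave their health region, by state.

    Restricted to travelers: the numerator counts those whose destination
    lies in a different health region than their residence, the denominator
    all travelers resident in the state (traveler-weighted pooling over
    municipalities). States where every traveler stays in-region score 0; a
    state with no travelers is NaN.
    """
    b = births if year is None else births[births["year"] == year]
    b = b[b["residence_muni"] != b["birth_muni"]].copy()
    lut = region_map.frame.set_index("muni")
    missing = sorted(
        (set(b["residence_muni"]) | set(b["birth_muni"])) - set(lut.index)
    )
    if missing:
        raise ValueError(f"municipalities missing from region map: {missing}")
    b["state"] = b["residence_muni"].map(lut["state"])
    b["origin_region"] = b["residence_muni"].map(lut["region"])
    b["dest_region"] = b["birth_muni"].map(lut["region"])
    b["exits"] = b["origin_region"] != b["dest_region"]
    out = (
        b.groupby(["state", "year"], sort=True)
        .agg(n_travelers=("exits", "size"), n_exit=("exits", "sum"))
        .reset_index()
        .rename(columns={"state": "unit"})
    )
    out["exit_share"] = out["n_exit"] / out["n_travelers"]
    return out
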