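"""Decomposition of the change in unconditional distance between periods.

Because ``D = F x C``, the change in D between two years splits exactly as

    dD = dF * C0  +  F0 * dC  +  dF * dC

where the first term is the contribution of more women traveling (at
baseline trip lengths), the second the contribution of longer trips (at the
baseline traveler share), and the third their interaction. The customary
two-term approximation ``dD ~ dF*C0 + F0*dC`` omits the interaction; this
module always reports all three, so the approximation error is exactly the
interaction term and the identity holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DecompositionResult", "decompose", "decompose_all"]


@dataclass
class DecompositionResult:
    """Exact three-term split of a D change for one unit.

    ``approx`` (term_share + term_length) is the two-term approximation;
    its error equals ``interaction`` by construction. ``defined`` is False
    when C is undefined (no travelers) in either year, in which case the
    terms are NaN rather than silently dropped.
    """

    unit: str
    t0: int
    t1: int
    delta_d: float
    term_share: float      # dF * C0 — more women traveling
    term_length: float     # F0 * dC — longer trips
    interaction: float     # dF * dC
    defined: bool = True

    @property
    def approx(self) -> float:
        return self.term_share + self.term_length

    @property
    def approx_error(self) -> float:
        return self.interaction


def _row_value(summary, col):
    if isinstance(summary, pd.Series):
        return summary[col]
    return getattr(summary, col)


def decompose(summary_t0, summary_t1) -> DecompositionResult:
    """Decompose the D change of one unit between two summaries.

    Accepts two access-summary rows (pandas Series with columns
    ``unit, year, f, c, d`` or any object with those attributes) for the
    same unit. Raises on a unit mismatch; returns a flagged-undefined
    result when C is undefined in either year.
    """
    u0, u1 = _row_value(summary_t0, "unit"), _row_value(summary_t1, "unit")
    if u0 != u1:
        raise ValueError(f"unit mismatch: {u0!r} vs {u1!r}")
    t0, t1 = int(_row_value(summary_t0, "year")), int(_row_value(summary_t1, "year"))
    f0, f1 = float(_row_value(summary_t0, "f")), float(_row_value(summary_t1, "f"))
    c0, c1 = float(_row_value(summary_t0, "c")), float(_row_value(summary_t1, "c"))

    if np.isnan(c0) or np.isnan(c1):
        return DecompositionResult(
            unit=u0, t0=t0, t1=t1, delta_d=np.nan, term_share=np.nan,
            term_length=np.nan, interaction=np.nan, defined=False,
        )
    df_, dc = f1 - f0, c1 - c0
    term_share = df_ * c0
    term_length = f0 * dc
    interaction = df_ * dc
    # delta computed from the same F*C products so the identity is exact
    delta_d = f1 * c1 - f0 * c0
    return DecompositionResult(
        unit=u0, t0=t0, t1=t1, delta_d=delta_d, term_share=term_share,
        term_length=term_length, interaction=interaction, defined=True,
    )


def decompose_all(
    access: pd.DataFrame, t0: int, t1: int
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Decompose every unit present in both years of an access table.

    Units present in only one year are excluded (listed in the medians
    block under ``excluded_units``); units with undefined C yield flagged
    rows that are omitted from the medians. Returns the per-unit table and
    cross-unit medians of each term.
    """
    a0 = access[access["year"] == t0].set_index("unit")
    a1 = access[access["year"] == t1].set_index("unit")
    common = sorted(set(a0.index) & set(a1.index))
    excluded = sorted(set(a0.index) ^ set(a1.index))

    rows = []
    for unit in common:
        r = decompose(
            _series_with_unit(a0.loc[unit], unit),
            _series_with_unit(a1.loc[unit], unit),
        )
        rows.append(
            {
                "unit": r.unit, "t0": r.t0, "t1": r.t1, "delta_d": r.delta_d,
                "term_share": r.term_share, "term_length": r.term_length,
                "interaction": r.interaction, "approx": r.approx,
                "defined": r.defined,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["unit", "t0", "t1", "delta_d", "term_share", "term_length",
                 "interaction", "approx", "defined"],
    )
    defined = table[table["defined"]] if len(table) else table
    medians = {
        "median_delta_d": float(defined["delta_d"].median()) if len(defined) else float("nan"),
        "median_term_share": float(defined["term_share"].median()) if len(defined) else float("nan"),
        "median_term_length": float(defined["term_length"].median()) if len(defined) else float("nan"),
        "median_interaction": float(defined["interaction"].median()) if len(defined) else float("nan"),
        "n_units": int(len(defined)),
        "excluded_units": excluded,
    }
    return table, medians


def _series_with_unit(row: pd.Series, unit: str) -> pd.Series:
    s = row.copy()
    s["unit"] = unit
    return s
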