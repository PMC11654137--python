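"""Risk-factor distance gaps and municipal socioeconomic gradients.

Two complementary individual/ecological analyses:

* **Gaps** — split the births by the presence of a clinical or social
  characteristic (low 5-minute APGAR, multiple pregnancy, low birth
  weight, prematurity, any pregnancy risk, maternal schooling, cesarean,
  prenatal-care intensity) and compare the mean distance traveled between
  the two groups, with a Welch standard error and normal 95% CI. Distance
  is unconditional by default: non-travelers count 0 km, so the gap reads
  as a difference in the population mean D.

* **Gradients** — regress the municipal mean distance D_i on one z-scored
  census covariate at a time, D_i = b0 + b1 * z(X_i) + e_i.  b1 is the
  extra kilometres associated with one standard deviation of the
  covariate; z-scoring makes magnitudes comparable across covariates and
  immunises b1 against covariate rescaling. Deliberately univariate and
  descriptive — no mutual adjustment, no causal reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_model import FLAG_COLUMNS, DistanceMatrix, attach_distance

__all__ = [
    "GapResult",
    "RegressionResult",
    "risk_factor_gaps",
    "fit_univariate",
    "gradient_panel",
]


@dataclass
class GapResult:
    factor: str
    mean_d_yes: float
    mean_d_no: float
    gap: float
    se_gap: float
    ci_lo: float
    ci_hi: float
    n_yes: int
    n_no: int
    defined: bool = True


@dataclass
class RegressionResult:
    """OLS of municipal D on one z-scored covariate."""

    covariate: str
    beta0: float
    beta1: float           # km per SD of the raw covariate
    se_beta1: float
    n: int
    mean_x: float
    sd_x: float
    ddof: int


def risk_factor_gaps(
    births: pd.DataFrame,
    dmat: DistanceMatrix,
    factors: tuple[str, ...] = FLAG_COLUMNS,
    conditional: bool = False,
) -> pd.DataFrame:
    """Mean-distance difference between flag-yes and flag-no groups.

    Per factor, records with that flag missing are excluded (for that
    factor only), as are travelers whose distance is unresolvable. The gap
    is mean(yes) - mean(no) with Welch SE ``sqrt(s1^2/n1 + s0^2/n0)``
    (sample variances) and a normal 95% CI. ``conditional=True`` restricts
    to travelers, turning the contrast into a difference in C.
    An empty group yields a flagged-undefined row.
    """
    annotated, _ = attach_distance(births, dmat)
    usable = annotated[annotated["distance_km"].notna()]
    if conditional:
        usable = usable[usable["traveled"]]
    z = stats.norm.ppf(0.975)

    rows = []
    for factor in factors:
        if factor not in usable.columns:
            continue
        known = usable[usable[factor].notna()]
        yes = known.loc[known[factor].astype(bool), "distance_km"].to_numpy(float)
        no = known.loc[~known[factor].astype(bool), "distance_km"].to_numpy(float)
        if len(yes) == 0 or len(no) == 0:
            rows.append(
                dict(factor=factor, mean_d_yes=np.nan, mean_d_no=np.nan, gap=np.nan,
                     se_gap=np.nan, ci_lo=np.nan, ci_hi=np.nan,
                     n_yes=len(yes), n_no=len(no), defined=False)
            )
            continue
        m1, m0 = yes.mean(), no.mean()
        v1 = yes.var(ddof=1) if len(yes) > 1 else 0.0
        v0 = no.var(ddof=1) if len(no) > 1 else 0.0
        se = float(np.sqrt(v1 / len(yes) + v0 / len(no)))
        gap = float(m1 - m0)
        rows.append(
            dict(factor=factor, mean_d_yes=float(m1), mean_d_no=float(m0), gap=gap,
                 se_gap=se, ci_lo=gap - z * se, ci_hi=gap + z * se,
                 n_yes=len(yes), n_no=len(no), defined=True)
        )
    return pd.DataFrame(
        rows,
        columns=["factor", "mean_d_yes", "mean_d_no", "gap", "se_gap",
                 "ci_lo", "ci_hi", "n_yes", "n_no", "defined"],
    )


def fit_univariate(
    d, x, covariate: str = "x", ddof: int = 1
) -> RegressionResult:
    """OLS of municipal distance on one z-scored covariate.

    ``ddof`` pins the standard-deviation convention used for the z-score
    (1 = sample, 0 = population); the slope equals ``corr(X, D) * sd(D)``
    under the matching convention. Pairs with a missing value on either
    side are dropped; fewer than 3 complete pairs or a constant covariate
    is an error.
    """
    d = np.asarray(d, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = ~(np.isnan(d) | np.isnan(x))
    d, x = d[keep], x[keep]
    if len(d) < 3:
        raise ValueError(f"{covariate}: need >=3 complete pairs, have {len(d)}")
    mean_x, sd_x = float(x.mean()), float(x.std(ddof=ddof))
    if sd_x == 0:
        raise ValueError(f"{covariate}: constant covariate, z-score undefined")
    xz = (x - mean_x) / sd_x
    fit = sm.OLS(d, sm.add_constant(xz)).fit()
    return RegressionResult(
        covariate=covariate,
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        se_beta1=float(fit.bse[1]),
        n=len(d),
        mean_x=mean_x,
        sd_x=sd_x,
        ddof=ddof,
    )


def gradient_panel(
    access_table: pd.DataFrame,
    census: pd.DataFrame,
    covariates: list[str] | None = None,
    ddof: int = 1,
    weighted: bool = False,
) -> pd.DataFrame:
    """One univariate regression per covariate, ordered by |beta1|.

    ``access_table`` is a municipal access table (one row per municipality;
    pool years first with ``muni_access(..., by_year=False)`` or filter one
    year). ``weighted=True`` weights municipalities by births (WLS).
    Covariates failing the fit preconditions are skipped with a note
    column rather than aborting the panel.
    """
    if covariates is None:
        covariates = [c for c in census.columns if c != "muni"]
    merged = access_table.merge(census, left_on="unit", right_on="muni", how="inner")
    rows = []
    for cov in covariates:
        try:
            if weighted:
                r = _fit_weighted(
                    merged["d"], merged[cov], merged["n_births"], cov, ddof
                )
            else:
                r = fit_univariate(merged["d"], merged[cov], cov, ddof)
            rows.append(
                dict(covariate=cov, beta0=r.beta0, beta1=r.beta1,
                     se_beta1=r.se_beta1, n=r.n, sign=float(np.sign(r.beta1)),
                     note="")
            )
        except ValueError as exc:
            rows.append(
                dict(covariate=cov, beta0=np.nan, beta1=np.nan, se_beta1=np.nan,
                     n=0, sign=np.nan, note=str(exc))
            )
    panel = pd.DataFrame(
        rows, columns=["covariate", "beta0", "beta1", "se_beta1", "n", "sign", "note"]
    )
    order = panel["beta1"].abs().fillna(-1.0)
    return panel.iloc[order.sort_values(ascending=False).index].reset_index(drop=True)


def _fit_weighted(d, x, w, covariate: str, ddof: int) -> RegressionResult:
    d = np.asarray(d, dtype=float)
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    keep = ~(np.isnan(d) | np.isnan(x))
    d, x, w = d[keep], x[keep], w[keep]
    if len(d) < 3:
        raise ValueError(f"{covariate}: need >=3 complete pairs, have {len(d)}")
    mean_x, sd_x = float(x.mean()), float(x.std(ddof=ddof))
    if sd_x == 0:
        raise ValueError(f"{covariate}: constant covariate, z-score undefined")
    xz = (x - mean_x) / sd_x
    fit = sm.WLS(d, sm.add_constant(xz), weights=w).fit()
    return RegressionResult(
        covariate=covariate, beta0=float(fit.params[0]), beta1=float(fit.params[1]),
        se_beta1=float(fit.bse[1]), n=len(d), mean_x=mean_x, sd_x=sd_x, ddof=ddof,
    )
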