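"""Synthetic birth-registry scenarios with known ground truth.

Real national birth registries and inter-municipal distance matrices are
restricted-access, so every downstream stage of this package is exercised on
simulated data that reproduces the statistical structure the analysis
relies on:

* a log-normal municipal birth-volume distribution (many small towns, a few
  large cities);
* hub-and-spoke referral geography — each health region has a dominant
  municipality (its largest) that concentrates delivery facilities and
  receives most travelers, producing the star-like flow pattern seen in
  administrative data;
* distance-decay travel probability: women in facility-owning towns are
  less likely to travel the farther the nearest alternative facility is;
  women in towns without any delivery facility always travel (institutional
  delivery is universal in the model);
* higher referral propensity for risk pregnancies (an additive log-odds
  boost to both traveling and choosing the regional hub);
* a socioeconomic gradient: a municipal development index correlated (with
  configurable sign and strength) with the town's distance burden, from
  which census-style covariates are derived.

Because the generator knows the model probabilities, it also emits exact
expected values (stratum travel probabilities, the risk-factor distance
gap) that the estimation pipeline can be checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_model import FLAG_COLUMNS, DistanceMatrix, RegionMap

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "Scenario",
    "generate_geography",
    "build_distance_matrix",
    "simulate_births",
    "generate_census",
    "simulate_scenario",
    "study_config",
    "recovery_config",
    "null_config",
]

_DEFAULT_RISK_RATES: dict[str, float] = {
    # Plausible placeholder prevalences; they carry no external authority
    # and nothing downstream depends on their exact values.
    "apgar5_lt8": 0.05,
    "multiple_pregnancy": 0.02,
    "low_birth_weight": 0.08,
    "preterm_lt37w": 0.11,
    "any_pregnancy_risk": 0.15,
    "edu_highschool_plus": 0.60,
    "cesarean": 0.55,
    "prenatal_7plus": 0.70,
}


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    Units: distances are kilometres; ``travel_slope_per_km`` and the trend
    fields act on the logit scale. ``dF_per_year`` shifts the travel-logit
    intercept per calendar year (raising the share of travelers F);
    ``dC_per_year`` shifts the hub-preference logit per year (lengthening
    trips, raising the conditional distance C).
    """

    n_munis: int = 120
    n_states: int = 6
    munis_per_region: int = 5
    size_mu: float = 3.5          # log-mean of annual births per municipality
    size_sigma: float = 1.0       # log-sd; >0 except in degenerate tests
    hub_fraction: float = 0.0     # extra hubs per region; >=1 hub always
    plane_extent_km: float = 800.0
    detour_factor: float = 1.3    # road km per straight-line km
    travel_intercept: float = -1.0
    travel_slope_per_km: float = -0.02
    facility_intercept: float = -4.0   # p(facility) = expit(a + b*log size)
    facility_slope_log_size: float = 1.1
    hub_logit: float = 0.4        # base log-odds a traveler heads to the hub
    risk_rates: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RISK_RATES)
    )
    risk_referral_boost: float = 0.6
    ses_gradient: float = -0.6    # corr(development index, distance burden)
    years: tuple[int, ...] = (2007, 2017)
    dF_per_year: float = 0.05
    dC_per_year: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_munis < self.n_states:
            raise ValueError("n_munis must be >= n_states")
        if self.size_sigma < 0:
            raise ValueError("size_sigma must be >= 0")
        if self.detour_factor < 1:
            raise ValueError("detour_factor must be >= 1")
        if not -1.0 <= self.ses_gradient <= 1.0:
            raise ValueError("ses_gradient must lie in [-1, 1]")
        for name, rate in self.risk_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"risk rate {name}={rate} outside [0, 1]")
        if len(self.years) < 1:
            raise ValueError("at least one year required")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "years" in d:
            d["years"] = tuple(int(y) for y in d["years"])
        return cls(**d)

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Exact quantities implied by the generated scenario.

    ``expected_*`` values are model expectations computed from the
    generator's own probabilities (independent of the realized random draw);
    ``realized_*`` values are recomputed directly from the generated records
    by straight array arithmetic.
    """

    expected_f_facility: float      # mean travel prob, births in facility-owning munis
    expected_f_no_facility: float   # always 1.0 (forced travel)
    realized_f_facility: float
    realized_f_no_facility: float
    n_births_facility: int
    n_births_no_facility: int
    expected_gap_any_risk: float    # expected D(yes) - D(no), km
    realized_gap_any_risk: float
    realized_gaps: dict[str, float]
    ses_gradient: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Scenario:
    """A fully generated scenario: inputs plus ground truth."""

    config: ScenarioConfig
    munis: pd.DataFrame
    region_map: RegionMap
    dmat: DistanceMatrix
    births: pd.DataFrame
    census: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# geography


def generate_geography(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, RegionMap]:
    """Place municipalities on a plane and organise them into states/regions.

    Municipalities are uniform on a ``plane_extent_km`` square. States are
    contiguous west-to-east bands of equal municipality count; within a
    state, regions are contiguous south-to-north chunks of
    ``munis_per_region`` municipalities, which guarantees region-in-state
    nesting. Annual birth volume is log-normal. The largest municipality of
    each region is its hub; hubs always own a delivery facility, other
    municipalities own one with probability logistic in log-size.

    Returns a municipality table (code, x_km, y_km, size, state, region,
    is_hub, has_facility) and the matching :class:`RegionMap`.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_munis

    codes = np.array([f"{i + 1:06d}" for i in range(n)], dtype=object)
    x = rng.uniform(0, config.plane_extent_km, n)
    y = rng.uniform(0, config.plane_extent_km, n)
    size = rng.lognormal(config.size_mu, config.size_sigma, n)

    munis = pd.DataFrame({"muni": codes, "x_km": x, "y_km": y, "size": size})

    # States: equal-count contiguous bands by longitude.
    order_x = munis.sort_values(["x_km", "muni"]).index
    state_labels = np.empty(n, dtype=object)
    for s, chunk in enumerate(np.array_split(order_x, config.n_states)):
        state_labels[chunk] = f"S{s + 1:02d}"
    munis["state"] = state_labels

    # Regions: contiguous latitude chunks within each state.
    region_labels = np.empty(n, dtype=object)
    for state, group in munis.groupby("state"):
        order_y = group.sort_values(["y_km", "muni"]).index
        n_regions = max(1, round(len(group) / config.munis_per_region))
        for r, chunk in enumerate(np.array_split(order_y, n_regions)):
            region_labels[chunk] = f"{state}R{r + 1:02d}"
    munis["region"] = region_labels

    # Hubs: the largest municipality of each region, plus extras per
    # hub_fraction (fraction of the region's municipalities, rounded).
    munis["is_hub"] = False
    for _, group in munis.groupby("region"):
        k = max(1, int(round(config.hub_fraction * len(group))))
        top = group.sort_values(["size", "muni"], ascending=[False, True]).index[:k]
        munis.loc[top, "is_hub"] = True

    p_fac = expit(
        config.facility_intercept
        + config.facility_slope_log_size * np.log(munis["size"].to_numpy())
    )
    munis["has_facility"] = munis["is_hub"].to_numpy() | (rng.uniform(size=n) < p_fac)

    region_map = RegionMap(munis[["muni", "state", "region"]])
    return munis.reset_index(drop=True), region_map


def build_distance_matrix(
    munis: pd.DataFrame, detour_factor: float = 1.3
) -> DistanceMatrix:
    """All-pairs road distances: detour_factor x Euclidean, zero diagonal."""
    if detour_factor < 1:
        raise ValueError("detour_factor must be >= 1")
    xy = munis[["x_km", "y_km"]].to_numpy()
    diff = xy[:, None, :] - xy[None, :, :]
    d = detour_factor * np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix.from_square(munis["muni"].tolist(), d)


# ---------------------------------------------------------------------------
# destination structure shared by the simulator and the expectation formulas


def _destination_structure(munis: pd.DataFrame, dmat: DistanceMatrix) -> pd.DataFrame:
    """Per municipality: nearest other facility and effective hub target.

    ``alt_muni``/``alt_km`` is the nearest facility-owning municipality other
    than the town itself. ``hub_muni``/``hub_km`` is the region's largest hub
    — or, for the hub itself, its nearest alternative facility (a hub
    resident who travels must leave town).
    """
    codes = munis["muni"].tolist()
    idx = {c: i for i, c in enumerate(codes)}
    n = len(codes)
    square = np.full((n, n), np.inf)
    f = dmat.frame
    square[
        f["origin"].map(idx).to_numpy(), f["destination"].map(idx).to_numpy()
    ] = f["km"].to_numpy()

    fac = munis["has_facility"].to_numpy()
    if not fac.any():
        raise ValueError("scenario has no facility-owning municipality")
    masked = square[:, fac].copy()
    fac_codes = np.asarray(codes, dtype=object)[fac]
    # exclude self from the alternatives
    self_cols = {idx[c]: j for j, c in enumerate(fac_codes)}
    for i in range(n):
        if fac[i]:
            masked[i, self_cols[i]] = np.inf
    alt_j = masked.argmin(axis=1)
    alt_km = masked[np.arange(n), alt_j]
    alt_muni = fac_codes[alt_j]

    # region hub: largest hub of the municipality's region
    hubs = munis[munis["is_hub"]]
    main_hub = (
        hubs.sort_values(["size", "muni"], ascending=[False, True])
        .groupby("region")
        .head(1)
        .set_index("region")["muni"]
    )
    hub_muni = munis["region"].map(main_hub).to_numpy(dtype=object)
    # a hub's own travel target falls back to its nearest alternative
    own = hub_muni == munis["muni"].to_numpy()
    hub_muni[own] = alt_muni[own]
    hub_km = square[np.arange(n), [idx[c] for c in hub_muni]]

    return pd.DataFrame(
        {
            "muni": codes,
            "alt_muni": alt_muni,
            "alt_km": alt_km,
            "hub_muni": hub_muni,
            "hub_km": hub_km,
        }
    )


def _travel_prob(config: ScenarioConfig, alt_km, risk, year) -> np.ndarray:
    """Model probability of traveling, facility-owning municipalities."""
    t = year - min(config.years)
    return expit(
        config.travel_intercept
        + config.travel_slope_per_km * alt_km
        + config.risk_referral_boost * risk
        + config.dF_per_year * t
    )


def _hub_prob(config: ScenarioConfig, risk, year) -> np.ndarray:
    """Model probability a traveler heads to the regional hub."""
    t = year - min(config.years)
    return expit(
        config.hub_logit + config.risk_referral_boost * risk + config.dC_per_year * t
    )


# ---------------------------------------------------------------------------
# births


def simulate_births(
    munis: pd.DataFrame,
    dmat: DistanceMatrix,
    config: ScenarioConfig,
    year: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one year of birth records.

    Per municipality the birth count is Poisson in its size. Every birth is
    institutional: residents of facility-less towns always travel; residents
    of facility-owning towns travel with probability
    ``logit^-1(intercept + slope*d_alt + boost*any_risk + dF*t)`` where
    ``d_alt`` is the distance to the nearest alternative facility. A
    traveler's destination is the regional hub with probability
    ``logit^-1(hub_logit + boost*any_risk + dC*t)``, otherwise the nearest
    facility. Flags are independent Bernoulli draws at ``risk_rates``.
    """
    dest = _destination_structure(munis, dmat)
    counts = rng.poisson(munis["size"].to_numpy())
    total = int(counts.sum())

    rep = np.repeat(np.arange(len(munis)), counts)
    residence = munis["muni"].to_numpy(dtype=object)[rep]
    has_fac = munis["has_facility"].to_numpy()[rep]
    alt_km = dest["alt_km"].to_numpy()[rep]
    alt_muni = dest["alt_muni"].to_numpy(dtype=object)[rep]
    hub_muni = dest["hub_muni"].to_numpy(dtype=object)[rep]

    flags = {
        name: rng.uniform(size=total) < rate for name, rate in config.risk_rates.items()
    }
    risk = flags.get("any_pregnancy_risk", np.zeros(total, dtype=bool)).astype(float)

    p_travel = _travel_prob(config, alt_km, risk, year)
    travels = (rng.uniform(size=total) < p_travel) | ~has_fac

    p_hub = _hub_prob(config, risk, year)
    to_hub = rng.uniform(size=total) < p_hub
    destination = residence.copy()
    destination[travels & to_hub] = hub_muni[travels & to_hub]
    destination[travels & ~to_hub] = alt_muni[travels & ~to_hub]

    births = pd.DataFrame(
        {
            "birth_id": [f"{year}-{i:07d}" for i in range(total)],
            "year": year,
            "residence_muni": residence,
            "birth_muni": destination,
        }
    )
    for name in FLAG_COLUMNS:
        if name in flags:
            births[name] = pd.array(flags[name], dtype="boolean")
    return births


# ---------------------------------------------------------------------------
# census covariates


_CENSUS_RECIPES = {
    # monotone transforms of the development index; sign of the implied
    # distance gradient follows the sign of the coefficient on dev
    "development_index": lambda dev: dev,
    "income_pc": lambda dev: 800.0 * np.exp(0.45 * dev),
    "hdi_education": lambda dev: np.clip(0.62 + 0.09 * dev, 0.0, 1.0),
    "hdi_income": lambda dev: np.clip(0.66 + 0.08 * dev, 0.0, 1.0),
    "child_poverty": lambda dev: 100.0 * expit(-0.9 * dev - 0.2),
    "illiteracy": lambda dev: 100.0 * expit(-0.8 * dev - 1.4),
    "poverty": lambda dev: 100.0 * expit(-0.9 * dev - 0.7),
}


def generate_census(
    munis: pd.DataFrame,
    dmat: DistanceMatrix,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Municipal covariates with a controlled distance gradient.

    A latent development index is built with correlation ``ses_gradient``
    against the town's distance burden (kilometres to the nearest delivery
    facility, 0 for facility owners); census-style indicators are monotone
    transforms of the index. ``ses_gradient < 0`` therefore means more
    developed towns face shorter distances — income-like covariates get
    negative distance slopes, poverty-like covariates positive ones.
    """
    dest = _destination_structure(munis, dmat)
    burden = np.where(munis["has_facility"].to_numpy(), 0.0, dest["alt_km"].to_numpy())
    sd = burden.std()
    z = (burden - burden.mean()) / sd if sd > 0 else np.zeros_like(burden)
    g = config.ses_gradient
    dev = g * z + np.sqrt(max(0.0, 1.0 - g**2)) * rng.standard_normal(len(munis))

    census = pd.DataFrame({"muni": munis["muni"]})
    for name, recipe in _CENSUS_RECIPES.items():
        census[name] = recipe(dev)
    return census


# ---------------------------------------------------------------------------
# full scenario with ground truth


def _expected_distance(
    config: ScenarioConfig, dest: pd.DataFrame, has_fac: np.ndarray, risk: float, year: int
) -> np.ndarray:
    """Expected unconditional km per birth, by municipality and risk status."""
    p_hub = float(_hub_prob(config, np.array(risk), year))
    trip = p_hub * dest["hub_km"].to_numpy() + (1 - p_hub) * dest["alt_km"].to_numpy()
    p_travel = _travel_prob(config, dest["alt_km"].to_numpy(), np.array(risk), year)
    p_travel = np.where(has_fac, p_travel, 1.0)
    return p_travel * trip


def _compute_truth(
    config: ScenarioConfig,
    munis: pd.DataFrame,
    dmat: DistanceMatrix,
    births: pd.DataFrame,
) -> GroundTruth:
    dest = _destination_structure(munis, dmat)
    has_fac = munis["has_facility"].to_numpy()
    weights = munis["size"].to_numpy()  # Poisson means = expected birth counts

    # expected stratum travel probability, birth-weighted over munis/years
    risk_rate = config.risk_rates.get("any_pregnancy_risk", 0.0)
    num_fac, den_fac = 0.0, 0.0
    exp_d_yes, exp_d_no = 0.0, 0.0
    for year in config.years:
        for risk, w_risk in ((1.0, risk_rate), (0.0, 1.0 - risk_rate)):
            p = _travel_prob(config, dest["alt_km"].to_numpy(), np.array(risk), year)
            num_fac += w_risk * float((weights[has_fac] * p[has_fac]).sum())
        den_fac += float(weights[has_fac].sum())
        e_yes = _expected_distance(config, dest, has_fac, 1.0, year)
        e_no = _expected_distance(config, dest, has_fac, 0.0, year)
        exp_d_yes += float((weights * e_yes).sum() / weights.sum())
        exp_d_no += float((weights * e_no).sum() / weights.sum())
    n_years = len(config.years)
    expected_f_facility = num_fac / den_fac if den_fac else float("nan")
    expected_gap = (exp_d_yes - exp_d_no) / n_years

    # realized values straight from the records
    fac_by_muni = munis.set_index("muni")["has_facility"]
    b = births.copy()
    b["has_fac"] = b["residence_muni"].map(fac_by_muni).astype(bool)
    b["traveled"] = b["residence_muni"] != b["birth_muni"]
    km = dmat.frame.set_index(["origin", "destination"])["km"]
    idx = pd.MultiIndex.from_arrays([b["residence_muni"], b["birth_muni"]])
    b["km"] = np.where(b["traveled"], km.reindex(idx).to_numpy(), 0.0)

    def _stratum_f(mask: pd.Series) -> float:
        return float(b.loc[mask, "traveled"].mean()) if mask.any() else float("nan")

    realized_gaps = {}
    for name in FLAG_COLUMNS:
        if name in b.columns:
            yes = b.loc[b[name] == True, "km"]  # noqa: E712 (nullable boolean)
            no = b.loc[b[name] == False, "km"]  # noqa: E712
            if len(yes) and len(no):
                realized_gaps[name] = float(yes.mean() - no.mean())

    return GroundTruth(
        expected_f_facility=expected_f_facility,
        expected_f_no_facility=1.0,
        realized_f_facility=_stratum_f(b["has_fac"]),
        realized_f_no_facility=_stratum_f(~b["has_fac"]),
        n_births_facility=int(b["has_fac"].sum()),
        n_births_no_facility=int((~b["has_fac"]).sum()),
        expected_gap_any_risk=expected_gap,
        realized_gap_any_risk=realized_gaps.get("any_pregnancy_risk", float("nan")),
        realized_gaps=realized_gaps,
        ses_gradient=config.ses_gradient,
    )


def study_config(seed: int = 0) -> ScenarioConfig:
    """The full-scale study scenario: ~50,000 births over two years.

    250 municipalities with log-normal volumes averaging ~95 annual births
    each; rising travel propensity and hub preference over the decade; a
    positive referral boost for risk pregnancies; a negative development
    gradient (more developed towns sit nearer facilities). These are the
    conditions every headline quantity in this package is computed under.
    """
    return ScenarioConfig(
        n_munis=250,
        n_states=8,
        munis_per_region=5,
        size_mu=4.05,
        size_sigma=1.0,
        seed=seed,
    )


def recovery_config(seed: int = 0) -> ScenarioConfig:
    """Reduced scenario (~5,000 births) for replicate-based sign recovery."""
    return ScenarioConfig(
        n_munis=60,
        n_states=4,
        munis_per_region=5,
        size_mu=3.3,
        size_sigma=1.0,
        seed=seed,
    )


def null_config(seed: int = 0) -> ScenarioConfig:
    """Fully stationary zero-effect scenario for null calibration.

    No risk referral boost, no socioeconomic gradient and no temporal
    trends in either travel propensity or hub preference, so the risk gap,
    every distance gradient and the trip-length decomposition term are all
    exact nulls and their estimates must center on zero across replicates.
    """
    return ScenarioConfig(
        n_munis=50,
        n_states=4,
        munis_per_region=5,
        size_mu=3.2,
        size_sigma=1.0,
        risk_referral_boost=0.0,
        ses_gradient=0.0,
        dF_per_year=0.0,
        dC_per_year=0.0,
        seed=seed,
    )


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate a complete scenario: geography, distances, births, census.

    Deterministic in ``config.seed``: identical configs produce
    byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    munis, region_map = generate_geography(config, rng)
    dmat = build_distance_matrix(munis, config.detour_factor)
    births = pd.concat(
        [simulate_births(munis, dmat, config, year, rng) for year in config.years],
        ignore_index=True,
    )
    census = generate_census(munis, dmat, config, rng)
    truth = _compute_truth(config, munis, dmat, births)
    return Scenario(config, munis, region_map, dmat, births, census, truth)
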