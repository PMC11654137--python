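import numpy as np
import pandas as pd
import pytest

from natalflow import DistanceMatrix, ScenarioConfig, simulate_scenario


def births_frame(rows, year=2010):
    """Build a birth registry from (residence, destination[, flags]) tuples."""
    records = []
    for i, row in enumerate(rows):
        res, dst = row[0], row[1]
        flags = row[2] if len(row) > 2 else {}
        rec = {"birth_id": f"b{i}", "year": year, "residence_muni": res,
               "birth_muni": dst}
        rec.update(flags)
        records.append(rec)
    df = pd.DataFrame(records)
    for col in df.columns:
        if col not in {"birth_id", "year", "residence_muni", "birth_muni"}:
            df[col] = df[col].astype("boolean")
    return df


@pytest.fixture
def dmat_abc():
    """Three municipalities with asymmetric road distances."""
    return DistanceMatrix.from_entries(
        {
            ("A", "A"): 0.0, ("B", "B"): 0.0, ("C", "C"): 0.0,
            ("A", "B"): 20.0, ("B", "A"): 22.0,
            ("A", "C"): 10.0, ("C", "A"): 10.0,
            ("B", "C"): 15.0, ("C", "B"): 15.0,
        }
    )


@pytest.fixture(scope="session")
def small_scenario():
    """A modest but fully structured scenario shared across tests."""
    return simulate_scenario(ScenarioConfig(n_munis=60, n_states=4, seed=11))


def random_tiny_config(rng: np.random.Generator) -> ScenarioConfig:
    """Draw a small random scenario configuration (for property suites)."""
    return ScenarioConfig(
        n_munis=int(rng.integers(8, 25)),
        n_states=int(rng.integers(2, 5)),
        munis_per_region=int(rng.integers(2, 5)),
        size_mu=float(rng.uniform(1.5, 2.8)),
        size_sigma=float(rng.uniform(0.3, 1.2)),
        detour_factor=float(rng.uniform(1.0, 1.6)),
        travel_intercept=float(rng.uniform(-2.0, 0.5)),
        travel_slope_per_km=float(rng.uniform(-0.04, 0.0)),
        hub_logit=float(rng.uniform(-0.5, 1.5)),
        risk_referral_boost=float(rng.uniform(0.0, 1.0)),
        ses_gradient=float(rng.uniform(-0.9, 0.9)),
        dF_per_year=float(rng.uniform(-0.05, 0.1)),
        dC_per_year=float(rng.uniform(-0.05, 0.1)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
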