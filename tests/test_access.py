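"""Access metrics: F/C/D identities, aggregation, Gini, brackets, deciles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from natalflow import (
    DistanceMatrix,
    RegionMap,
    aggregate,
    decile_summary,
    gini,
    gini_conditional_distance,
    muni_access,
    percentile_brackets,
)

from conftest import births_frame


def _rmap(*rows):
    return RegionMap(pd.DataFrame(rows, columns=["muni", "state", "region"]))


class TestMuniAccess:
    def test_quarter_travelers_hand_arithmetic(self, dmat_abc):
        births = births_frame([("A", "A"), ("A", "A"), ("A", "A"), ("A", "B")])
        row = muni_access(births, dmat_abc).iloc[0]
        assert row["f"] == pytest.approx(0.25)
        assert row["c"] == pytest.approx(20.0)
        assert row["d"] == pytest.approx(5.0)

    def test_all_local_c_undefined_d_zero(self, dmat_abc):
        births = births_frame([("A", "A"), ("A", "A")])
        row = muni_access(births, dmat_abc).iloc[0]
        assert row["f"] == 0.0
        assert np.isnan(row["c"])
        assert row["d"] == 0.0

    def test_all_travel_identity_case(self, dmat_abc):
        births = births_frame([("C", "A"), ("C", "A"), ("C", "A")])
        row = muni_access(births, dmat_abc).iloc[0]
        assert row["f"] == 1.0
        assert row["c"] == pytest.approx(10.0)
        assert row["d"] == pytest.approx(10.0)

    def test_unresolved_traveler_excluded_from_c_counted(self, dmat_abc):
        births = births_frame([("A", "B"), ("A", "Z"), ("A", "A"), ("A", "A")])
        row = muni_access(births, dmat_abc).iloc[0]
        assert row["n_distance_missing"] == 1
        assert row["f"] == pytest.approx(0.5)  # both travelers count in F
        assert row["c"] == pytest.approx(20.0)  # only the resolved one in C

    def test_empty_muni_year_emits_no_row(self, dmat_abc):
        births = births_frame([("A", "A")])
        table = muni_access(births, dmat_abc)
        assert set(table["unit"]) == {"A"}


class TestAggregate:
    def _table(self, rows):
        cols = ["unit", "year", "n_births", "n_travelers", "n_distance_missing",
                "traveler_km", "f", "c", "d"]
        return pd.DataFrame(rows, columns=cols)

    def test_equal_weight_mean(self):
        t = self._table([
            ("A", 2010, 100, 0, 0, 0.0, 0.0, np.nan, 0.0),
            ("B", 2010, 100, 50, 0, 2000.0, 0.5, 40.0, 20.0),
        ])
        # pooled: D = total km / total births = 2000/200 = 10
        out = aggregate(t, "state", _rmap(("A", "S1", "R1"), ("B", "S1", "R1")))
        assert out["d"].iloc[0] == pytest.approx(10.0)

    def test_birth_weighted_mean_of_d(self):
        t = self._table([
            ("A", 2010, 10, 0, 0, 0.0, 0.0, np.nan, 0.0),
            ("B", 2010, 190, 190, 0, 1900.0, 1.0, 10.0, 10.0),
        ])
        out = aggregate(t, "national")
        assert out["d"].iloc[0] == pytest.approx(9.5)

    def test_single_muni_state_equals_muni(self):
        t = self._table([("A", 2010, 7, 3, 0, 90.0, 3 / 7, 30.0, 90.0 / 7)])
        out = aggregate(t, "state", _rmap(("A", "S1", "R1")))
        for col in ("n_births", "n_travelers", "f", "c", "d"):
            assert out[col].iloc[0] == pytest.approx(t[col].iloc[0])

    def test_missing_muni_in_region_map_fatal(self):
        t = self._table([("A", 2010, 1, 0, 0, 0.0, 0.0, np.nan, 0.0)])
        with pytest.raises(ValueError, match="A"):
            aggregate(t, "state", _rmap(("B", "S1", "R1")))

    def test_associativity_and_identity(self, small_scenario):
        sc = small_scenario
        table = muni_access(sc.births, sc.dmat)
        states = aggregate(table, "state", sc.region_map)
        via_states = (
            states.groupby("year")
            .agg(
                n_births=("n_births", "sum"),
                n_travelers=("n_travelers", "sum"),
                traveler_km=("traveler_km", "sum"),
            )
            .reset_index()
        )
        direct = aggregate(table, "national")
        merged = direct.merge(via_states, on="year", suffixes=("", "_v"))
        assert np.allclose(merged["n_births"], merged["n_births_v"])
        assert np.allclose(merged["traveler_km"], merged["traveler_km_v"])
        for frame in (table, states, direct):
            defined = frame[frame["n_travelers"] > 0]
            assert np.allclose(defined["d"], defined["f"] * defined["c"], rtol=1e-9)

    def test_unweighted_variant_is_municipal_mean(self):
        t = self._table([
            ("A", 2010, 10, 5, 0, 100.0, 0.5, 20.0, 10.0),
            ("B", 2010, 1000, 100, 0, 1000.0, 0.1, 10.0, 1.0),
        ])
        out = aggregate(t, "national", weighted=False)
        assert out["f"].iloc[0] == pytest.approx(0.3)
        assert out["c"].iloc[0] == pytest.approx(15.0)
        assert out["d"].iloc[0] == pytest.approx(5.5)


class TestScaleBehaviour:
    def test_f_invariant_c_d_linear_in_distance_rescale(self, small_scenario):
        sc = small_scenario
        base = muni_access(sc.births, sc.dmat)
        scaled_frame = sc.dmat.frame.assign(km=sc.dmat.frame["km"] * 3.0)
        scaled = muni_access(sc.births, DistanceMatrix(scaled_frame))
        merged = base.merge(scaled, on=["unit", "year"], suffixes=("", "_s"))
        assert np.allclose(merged["f"], merged["f_s"])
        both = merged[merged["n_travelers"] > 0]
        assert np.allclose(both["c_s"], 3.0 * both["c"])
        assert np.allclose(both["d_s"], 3.0 * both["d"])


def brute_force_gini(x):
    x = np.asarray(x, dtype=float)
    n = len(x)
    return float(np.abs(x[:, None] - x[None, :]).sum() / (2 * n * n * x.mean()))


class TestGini:
    def test_equal_values_zero(self):
        assert gini([5.0, 5.0, 5.0]) == pytest.approx(0.0, abs=1e-12)

    def test_two_values_quarter(self):
        assert gini([1.0, 3.0]) == pytest.approx(0.25)

    def test_scale_invariance(self):
        x = [1.0, 4.0, 9.0, 16.0]
        assert gini([10 * v for v in x]) == pytest.approx(gini(x))

    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=2, max_size=200)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, values):
        assert gini(values) == pytest.approx(brute_force_gini(values), rel=1e-9)

    def test_weighted_reduces_to_replication(self):
        # integer weights == repeating each value that many times
        x, w = [2.0, 8.0, 5.0], [3, 1, 2]
        replicated = [2.0] * 3 + [8.0] + [5.0] * 2
        assert gini(x, w) == pytest.approx(gini(replicated))

    def test_fewer_than_two_values_undefined(self):
        assert np.isnan(gini([4.0]))

    def test_per_state_gini_flags_undefined(self, dmat_abc):
        births = births_frame([("A", "B"), ("B", "A"), ("C", "A")])
        table = muni_access(births, dmat_abc)
        rmap = _rmap(("A", "S1", "R1"), ("B", "S1", "R1"), ("C", "S2", "R2"))
        out = gini_conditional_distance(table, rmap).set_index("unit")
        assert out.loc["S1", "defined"]
        assert out.loc["S1", "gini"] == pytest.approx(
            brute_force_gini([20.0, 22.0])
        )
        assert not out.loc["S2", "defined"]
        assert np.isnan(out.loc["S2", "gini"])


def naive_bracket(values):
    """Rank-based oracle: bracket = which eighth of the pooled cuts v exceeds."""
    v = np.asarray(values, dtype=float)
    cuts = np.percentile(v, np.arange(12.5, 100.0, 12.5))
    return np.array([1 + int((cuts < x).sum()) for x in v])


class TestBrackets:
    def test_eight_distinct_values_one_per_bracket(self):
        scheme = percentile_brackets(np.arange(1.0, 9.0))
        assert scheme.assign(np.arange(1.0, 9.0)).tolist() == list(range(1, 9))

    def test_identical_values_collapse_to_bracket_one(self):
        scheme = percentile_brackets([7.0] * 12)
        assert scheme.assign([7.0] * 12).tolist() == [1] * 12

    def test_sixteen_equally_spaced_two_per_bracket(self):
        v = np.arange(1.0, 17.0)
        scheme = percentile_brackets(v)
        counts = np.bincount(scheme.assign(v), minlength=9)[1:]
        assert counts.tolist() == [2] * 8

    def test_matches_naive_ranking_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            v = rng.lognormal(3.0, 1.0, size=int(rng.integers(8, 120)))
            scheme = percentile_brackets(v)
            assert np.array_equal(scheme.assign(v), naive_bracket(v))


class TestDecileSummary:
    def test_ten_distinct_sizes_one_per_decile(self, dmat_abc):
        rows = []
        for i, n in enumerate(range(1, 11)):  # muni i has i+1 births
            code = f"M{i}"
            rows += [(code, code)] * n
        births = births_frame(rows)
        # distances never used (nobody travels) but the matrix must resolve
        dmat = DistanceMatrix.from_entries(
            {(f"M{i}", f"M{i}"): 0.0 for i in range(10)}
        )
        table = decile_summary(births, dmat)
        assert table["decile"].tolist() == list(range(1, 11))
        assert np.allclose(table["births_min"], table["births_max"])

    def test_zero_traveler_cell_c_undefined(self, dmat_abc):
        births = births_frame([("A", "A"), ("B", "A")])
        table = decile_summary(births, dmat_abc)
        first = table[table["decile"] == 1].iloc[0]
        assert np.isnan(first["c"]) or first["n_travelers"] > 0

    def test_f_declines_with_municipal_size(self, small_scenario):
        sc = small_scenario
        table = decile_summary(sc.births, sc.dmat)
        by_decile = table.groupby("decile")["f"].mean()
        # direction only: small municipalities travel far more often
        assert by_decile.loc[1] > by_decile.loc[10]
        # and the overall rank correlation is strongly negative
        corr = by_decile.corr(pd.Series(by_decile.index, index=by_decile.index),
                              method="spearman")
        assert corr < -0.5
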