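"""Aggregation reports: ee regimes, category distributions, combination
matrices, top-N rankings."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aho.records import ConfigError
from aho.stats import (
    category_distribution, combination_matrix, ee_regime_distribution,
    exact_median, top_n,
)


def _frame(rows):
    return pd.DataFrame(rows)


class TestEeRegimes:
    def test_right_closed_bins(self):
        df = _frame([{"ee": v} for v in (99, 97, 60, 20)])
        report = ee_regime_distribution(df, bin_edges=(70, 90))
        assert report.labels == ["<=70", "70-90", ">90"]
        assert report.counts == [2, 0, 2]
        assert report.fractions == [0.5, 0.0, 0.5]

    def test_boundary_value_falls_in_lower_bin(self):
        df = _frame([{"ee": 70.0}, {"ee": 70.0001}])
        report = ee_regime_distribution(df, bin_edges=(70, 90))
        assert report.counts == [1, 1, 0]

    def test_all_high(self):
        df = _frame([{"ee": 99.5}] * 7)
        report = ee_regime_distribution(df)
        assert report.counts[-1] == 7

    def test_missing_ee_excluded_and_counted(self):
        df = _frame([{"ee": 95}, {"ee": None}, {"ee": np.nan}])
        report = ee_regime_distribution(df)
        assert sum(report.counts) == 1
        assert report.n_excluded == 2

    def test_empty_input_is_empty_report(self):
        report = ee_regime_distribution(_frame([]))
        assert sum(report.counts) == 0

    def test_bad_edges_rejected(self):
        with pytest.raises(ConfigError):
            ee_regime_distribution(_frame([{"ee": 5}]), bin_edges=(90, 70))

    @given(st.lists(st.floats(min_value=0, max_value=100), max_size=60))
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_counts_conserved_for_any_sample(self, values):
        df = _frame([{"ee": v} for v in values])
        report = ee_regime_distribution(df)
        assert sum(report.counts) == len(values)
        if values:
            assert sum(report.fractions) == pytest.approx(1.0)


class TestCategoryDistribution:
    def _classified(self):
        rows = []
        rows += [{"metal": "Ir", "solvent": "dichloromethane"}] * 8
        rows += [{"metal": "Ir", "solvent": "toluene"}] * 2
        rows += [{"metal": "Rh", "solvent": "methanol"}] * 5
        return _frame(rows)

    def test_fractions(self):
        reports = category_distribution(self._classified(), "solvent",
                                        per_metal=True)
        ir = next(r for r in reports if r.metal == "Ir")
        assert dict(zip(ir.labels, ir.fractions))["dichloromethane"] == 0.8

    def test_metal_shares(self):
        rows = [{"metal": m} for m, k in
                (("Rh", 531), ("Ir", 379), ("Co", 10), ("Ru", 80))
                for _ in range(k)]
        report = category_distribution(_frame(rows), "metal")
        assert dict(zip(report.labels, report.fractions))["Rh"] == \
            pytest.approx(0.531)

    def test_top_n_with_other_remainder(self):
        rows = [{"metal": "Ir", "solvent": s}
                for s in list("AAAABBBCCD")]
        report = category_distribution(_frame(rows), "solvent", top_n=2)
        assert report.labels == ["A", "B", "other"]
        assert report.counts == [4, 3, 3]

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError):
            category_distribution(self._classified(), "nope")

    def test_row_order_invariance(self):
        df = self._classified().sample(frac=1.0, random_state=3)
        a = category_distribution(df, "solvent")
        b = category_distribution(self._classified(), "solvent")
        assert (a.labels, a.counts) == (b.labels, b.counts)


def _random_classified(rng, n):
    metals = rng.choice(["Ir", "Rh", "Co"], n)
    return _frame([{
        "metal": metals[i],
        "degree_label": rng.choice(["disubstituted", "trisubstituted"]),
        "primary_olefin_class": rng.choice(["aryl_alkyl", "enol"]),
        "ligand_category": rng.choice(["bisphosphine", "phosphine"]),
        "ee": float(rng.integers(0, 101)) if rng.random() > 0.1 else None,
    } for i in range(n)])


class TestCombinationMatrix:
    def test_even_n_median(self):
        df = _frame([
            {"metal": "Ir", "degree_label": "d", "primary_olefin_class": "c",
             "ligand_category": "l", "ee": 90.0},
            {"metal": "Ir", "degree_label": "d", "primary_olefin_class": "c",
             "ligand_category": "l", "ee": 80.0},
        ])
        (cell,) = combination_matrix(df, "Ir")
        assert cell.n_reactions == 2 and cell.median_ee == 85.0

    def test_single_record(self):
        df = _frame([{"metal": "Rh", "degree_label": "d",
                      "primary_olefin_class": "c", "ligand_category": "l",
                      "ee": 95.0}])
        (cell,) = combination_matrix(df, "Rh")
        assert cell.n_reactions == 1 and cell.median_ee == 95.0

    def test_against_brute_force_oracle(self):
        """Cell counts and medians vs an independent dict-and-sort oracle on
        randomized fixtures."""
        rng = np.random.default_rng(5)
        df = _random_classified(rng, 400)
        for metal in ("Ir", "Rh", "Co"):
            oracle: dict[tuple, list] = {}
            for row in df[df.metal == metal].to_dict("records"):
                key = (row["degree_label"], row["primary_olefin_class"],
                       row["ligand_category"])
                oracle.setdefault(key, []).append(row["ee"])
            cells = {(c.degree_label, c.primary_olefin_class,
                      c.ligand_category): c
                     for c in combination_matrix(df, metal)}
            assert set(cells) == set(oracle)
            for key, ees in oracle.items():
                vals = sorted(v for v in ees if pd.notna(v))
                assert cells[key].n_reactions == len(ees)
                if vals:
                    mid = len(vals) // 2
                    want = vals[mid] if len(vals) % 2 else \
                        (vals[mid - 1] + vals[mid]) / 2
                    assert cells[key].median_ee == want
                    assert vals[0] <= cells[key].median_ee <= vals[-1]
                else:
                    assert cells[key].median_ee is None

    def test_conservation(self):
        rng = np.random.default_rng(9)
        df = _random_classified(rng, 300)
        for metal in ("Ir", "Rh", "Co"):
            cells = combination_matrix(df, metal)
            assert sum(c.n_reactions for c in cells) == \
                int((df.metal == metal).sum())


class TestTopN:
    def _df(self):
        rows = [{"substrate_canonical": s, "ligand_canonical": "L"}
                for s in ["A"] * 5 + ["B"] * 3 + ["C"] * 3]
        return _frame(rows)

    def test_tie_broken_lexicographically(self):
        assert top_n(self._df(), "olefin", 2) == [("A", 5), ("B", 3)]

    def test_n_larger_than_universe(self):
        assert top_n(self._df(), "olefin", 10) == \
            [("A", 5), ("B", 3), ("C", 3)]

    def test_invalid_n(self):
        with pytest.raises(ConfigError):
            top_n(self._df(), "olefin", 0)

    def test_planted_top_structure_recovered(self, classified):
        """The generator's most frequent substrate tops the ranking."""
        expected = classified["substrate_canonical"].value_counts().idxmax()
        assert top_n(classified, "olefin", 1)[0][0] == expected


class TestExactMedian:
    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=1,
                    max_size=25))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_matches_sort_based_oracle(self, values):
        vals = sorted(values)
        mid = len(vals) // 2
        want = vals[mid] if len(vals) % 2 else (vals[mid-1] + vals[mid]) / 2
        assert exact_median(values) == pytest.approx(want)
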