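"""Predictor-subset funnel: enumeration, class filter, collinearity filter,
and AIC quartile-tally ranking."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nicheshift.occurrences import OccurrenceTable
from nicheshift.predictors import (
    enumerate_subsets,
    filter_class_balance,
    filter_collinearity,
    rank_by_quartile_tally,
)
from nicheshift.world.climate import ALL_VARS, VAR_CLASS


def brute_force_subsets(variables, lo, hi):
    out = []
    for k in range(lo, hi + 1):
        out.extend(combinations(sorted(variables), k))
    return out


class TestEnumerate:
    def test_eight_variables_sizes_3_to_8_yield_219(self):
        subs = enumerate_subsets(tuple(ALL_VARS), 3, 8)
        assert len(subs) == 219
        assert len({s.members for s in subs}) == 219

    def test_single_full_set(self):
        assert len(enumerate_subsets(("a", "b", "c"), 3, 3)) == 1

    def test_four_variables_sizes_2_to_4_yield_11(self):
        subs = enumerate_subsets(("a", "b", "c", "d"), 2, 4)
        oracle = brute_force_subsets(("a", "b", "c", "d"), 2, 4)
        assert len(subs) == len(oracle) == 11
        assert {s.members for s in subs} == set(oracle)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            enumerate_subsets(("a", "a", "b"), 2, 3)


class TestClassBalance:
    def test_paper_funnel_discards_10_retains_209(self):
        subs = enumerate_subsets(tuple(ALL_VARS), 3, 8)
        kept, discarded = filter_class_balance(subs)
        assert discarded == 10
        assert len(kept) == 209

    def test_single_class_triple_discarded(self):
        subs = enumerate_subsets(
            ("temp_mean", "temp_seasonality", "temp_max_warmest"), 3, 3
        )
        kept, discarded = filter_class_balance(subs)
        assert kept == [] and discarded == 1

    def test_two_by_two_sizes_2_to_4_discards_exactly_2(self):
        vars_ = ("temp_mean", "temp_seasonality", "prec_mean",
                 "prec_driest")
        subs = enumerate_subsets(vars_, 2, 4)
        kept, discarded = filter_class_balance(subs)
        # brute force over the 11 subsets
        oracle = sum(
            1 for m in brute_force_subsets(vars_, 2, 4)
            if len({VAR_CLASS[v] for v in m}) < 2
        )
        assert discarded == oracle == 2
        assert len(kept) == 9

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(n_temp=st.integers(1, 6), n_prec=st.integers(1, 6),
           lo=st.integers(1, 3))
    def test_counts_match_binomial_closed_form(self, n_temp, n_prec, lo):
        """enumerate + class filter counts equal the closed-form sum of
        binomials for any temperature/precipitation split."""
        from math import comb

        temps = tuple(f"t{i}" for i in range(n_temp))
        precs = tuple(f"p{i}" for i in range(n_prec))
        n = n_temp + n_prec
        hi = n
        subs = enumerate_subsets(temps + precs, lo, hi)
        class_of = {v: "temperature" for v in temps}
        class_of.update({v: "precipitation" for v in precs})
        kept, discarded = filter_class_balance(subs, class_of)
        total = sum(comb(n, k) for k in range(lo, hi + 1))
        single = sum(
            comb(n_temp, k) + comb(n_prec, k) for k in range(lo, hi + 1)
        )
        assert len(subs) == total
        assert discarded == single
        assert len(kept) == total - single


class TestCollinearity:
    def _sample(self, n=500, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.normal(size=(n, len(ALL_VARS))), columns=list(ALL_VARS)
        )
        return df

    def test_duplicated_variable_discards_containing_subsets(self):
        df = self._sample()
        df["temp_max_warmest"] = df["temp_mean"]  # r = 1 pair
        subs = enumerate_subsets(tuple(ALL_VARS), 3, 8)
        kept, _ = filter_collinearity(subs, df)
        for s in kept:
            assert not {"temp_mean", "temp_max_warmest"} <= set(s.members)
        dropped = [s for s in subs
                   if {"temp_mean", "temp_max_warmest"} <= set(s.members)]
        assert len(kept) == len(subs) - len(dropped)

    def test_boundary_r_exactly_0_7_retained(self):
        # construct two columns with sample correlation exactly 0.7
        n = 1000
        rng = np.random.default_rng(3)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        # orthonormalize then mix to hit r = 0.7 exactly
        a = (a - a.mean()) / a.std()
        b = b - b.mean()
        b -= a * (a @ b) / (a @ a)
        b /= b.std()
        y = 0.7 * a + np.sqrt(1 - 0.49) * b
        df = pd.DataFrame({"temp_mean": a, "prec_mean": y})
        r = df.corr().iloc[0, 1]
        assert r == pytest.approx(0.7, abs=1e-12)
        subs = enumerate_subsets(("temp_mean", "prec_mean"), 2, 2)
        kept, _ = filter_collinearity(subs, df)
        assert len(kept) == 1  # strict inequality: r > 0.7 discards

    def test_independent_variables_retain_all_209(self):
        df = self._sample(n=10_000, seed=7)
        subs, _ = filter_class_balance(enumerate_subsets(tuple(ALL_VARS), 3, 8))
        kept, _ = filter_collinearity(subs, df)
        assert len(kept) == 209

    def test_constant_variable_is_violation_and_reported(self):
        df = self._sample()
        df["prec_driest"] = 1.0
        subs = enumerate_subsets(tuple(ALL_VARS), 3, 8)
        kept, report = filter_collinearity(subs, df)
        for s in kept:
            assert "prec_driest" not in s.members
        assert report["constant"].any()

    def test_filter_is_monotone_adding_never_repairs(self):
        df = self._sample(seed=5)
        df["temp_max_warmest"] = df["temp_mean"] + 0.01 * df["prec_mean"]
        subs = enumerate_subsets(tuple(ALL_VARS), 3, 8)
        kept, _ = filter_collinearity(subs, df)
        kept_set = {s.members for s in kept}
        for s in subs:
            if s.members in kept_set:
                continue
            # every superset of a discarded subset is discarded
            for t in subs:
                if set(s.members) < set(t.members):
                    assert t.members not in kept_set


class TestQuartileTally:
    def _table(self, rng, truth_vars, n=300, noise=1.0):
        X = rng.normal(size=(n, len(ALL_VARS)))
        cols = {v: X[:, i] for i, v in enumerate(ALL_VARS)}
        eta = sum(2.0 * cols[v] for v in truth_vars) + noise * rng.normal(size=n)
        y = (eta > 0).astype(int)
        data = pd.DataFrame(cols)
        data.insert(0, "col", 0)
        data.insert(0, "row", 0)
        data["label"] = y
        data["block"] = pd.array([0] * n, dtype="Int64")
        return OccurrenceTable(species_id="sim", data=data)

    def test_single_candidate_trivially_wins(self):
        subs = enumerate_subsets(("temp_mean", "prec_mean"), 2, 2)
        rng = np.random.default_rng(0)
        tables = [self._table(rng, ("temp_mean",)) for _ in range(3)]
        tally = rank_by_quartile_tally(subs, tables)
        assert tally.counts[subs[0].members] == 3
        assert tally.winner == subs[0].members
        assert tally.winner_fraction == 1.0

    def test_truth_containing_subset_outscores_omitting_subsets(self):
        """Species built on {temp_mean, prec_mean}: any candidate holding
        both truth variables tallies more top-quartile appearances than any
        candidate omitting both."""
        rng = np.random.default_rng(1)
        cands = enumerate_subsets(
            ("temp_mean", "prec_mean", "temp_seasonality", "prec_driest"),
            2, 3,
        )
        tables = [
            self._table(rng, ("temp_mean", "prec_mean")) for _ in range(8)
        ]
        tally = rank_by_quartile_tally(cands, tables)
        with_truth = [c.members for c in cands
                      if {"temp_mean", "prec_mean"} <= set(c.members)]
        without = [c.members for c in cands
                   if not ({"temp_mean", "prec_mean"} & set(c.members))]
        best_with = max(tally.counts[m] for m in with_truth)
        for m in without:
            assert tally.counts[m] < best_with

    def test_tally_sum_identity(self):
        rng = np.random.default_rng(2)
        cands = enumerate_subsets(
            ("temp_mean", "prec_mean", "temp_seasonality", "prec_driest"),
            2, 3,
        )
        tables = [self._table(rng, ("temp_mean",)) for _ in range(4)]
        tally = rank_by_quartile_tally(cands, tables)
        q = int(np.ceil(len(cands) / 4))
        assert sum(tally.counts.values()) == len(tables) * q
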