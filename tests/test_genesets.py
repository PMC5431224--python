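import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from toxpipe.errors import UndefinedTestError, ValidationError
from toxpipe.genesets import (
    ColumnFilter,
    GeneSet,
    StatColumn,
    apply_filter,
    compute_stat_column,
    extract_consistent,
    filter_table,
    geneset_algebra,
    mann_whitney,
    welch_t,
)

from conftest import make_dataset
from toxpipe.core import SampleGroup


class TestColumnFilter:
    def test_rejects_unknown_kind(self):
        with pytest.raises(ValidationError):
            ColumnFilter("between", 1.0)

    def test_rejects_nonfinite_threshold(self):
        with pytest.raises(ValidationError):
            ColumnFilter("upper", float("nan"))


class TestApplyFilter:
    def test_lower_abs_boundary(self):
        mask = apply_filter([1.6, -1.6, 1.2], ColumnFilter("lower_abs", 1.5))
        assert mask.tolist() == [True, True, False]

    def test_upper_on_pvalues(self):
        mask = apply_filter([0.005, 0.05], ColumnFilter("upper", 0.01))
        assert mask.tolist() == [True, False]

    def test_inactive_passes_everything(self):
        mask = apply_filter([np.nan, -5.0, 100.0], ColumnFilter("upper", 0.0, active=False))
        assert mask.all()

    def test_missing_fails_active_filters(self):
        for kind in ("upper", "upper_abs", "lower", "lower_abs"):
            assert not apply_filter([np.nan], ColumnFilter(kind, 1e9)).any()

    @pytest.mark.parametrize("kind,value,expected", [
        ("upper", 1.5, True), ("upper", 1.6, False),
        ("upper_abs", -1.5, True), ("upper_abs", -1.6, False),
        ("lower", 1.5, True), ("lower", 1.4, False),
        ("lower_abs", -1.5, True), ("lower_abs", -1.4, False),
    ])
    def test_bounds_inclusive(self, kind, value, expected):
        assert apply_filter([value], ColumnFilter(kind, 1.5))[0] == expected


class TestFilterTable:
    @pytest.fixture
    def table(self):
        return pd.DataFrame({"fc": [1.5, 1.49, 2.0]}, index=["r1", "r2", "r3"])

    def test_boundary_inclusive(self, table):
        gs = filter_table(table, {"fc": ColumnFilter("lower", 1.5)})
        assert gs.members == ("r1", "r3")

    def test_empty_result_warns(self, table):
        with pytest.warns(UserWarning, match="empty"):
            gs = filter_table(table, {"fc": ColumnFilter("lower", 99.0)})
        assert gs.members == ()

    def test_unknown_column_errors(self, table):
        with pytest.raises(ValidationError, match="unknown filter columns"):
            filter_table(table, {"nope": ColumnFilter("lower", 1.0)})

    def test_matches_rowwise_bruteforce(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"),
                             index=[f"r{i}" for i in range(40)])
        filters = {"a": ColumnFilter("lower", 0.0),
                   "b": ColumnFilter("upper_abs", 1.0),
                   "c": ColumnFilter("upper", 0.5)}
        gs = filter_table(table, filters)
        expected = [
            r for r in table.index
            if table.loc[r, "a"] >= 0.0
            and abs(table.loc[r, "b"]) <= 1.0
            and table.loc[r, "c"] <= 0.5
        ]
        assert list(gs.members) == expected

    def test_conjunction_order_independent_and_idempotent(self):
        rng = np.random.default_rng(11)
        table = pd.DataFrame(rng.normal(size=(30, 2)), columns=["x", "y"],
                             index=[f"r{i}" for i in range(30)])
        f1 = {"x": ColumnFilter("lower", -0.5), "y": ColumnFilter("upper", 0.5)}
        f2 = {"y": ColumnFilter("upper", 0.5), "x": ColumnFilter("lower", -0.5)}
        a = filter_table(table, f1).members
        b = filter_table(table, f2).members
        assert a == b
        again = filter_table(table.loc[list(a)], f1).members
        assert again == a


class TestWelchT:
    def test_identical_groups(self):
        t, df, p = welch_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_known_value(self):
        t, df, p = welch_t([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.0 / math.sqrt(2.0 / 3.0), abs=1e-9)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_swap_flips_sign_keeps_p(self):
        t1, _, p1 = welch_t([1, 2, 3], [4, 5, 6])
        t2, _, p2 = welch_t([4, 5, 6], [1, 2, 3])
        assert t1 == -t2 and p1 == p2

    def test_against_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 10))
            t, df, p = welch_t(a, b)
            ref = sps.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_against_permutation_approximation(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=8)
        b = rng.normal(loc=0.8, size=8)
        t_obs, _, p = welch_t(a, b)
        pooled = np.concatenate([a, b])
        count = total = 0
        for combo in itertools.combinations(range(16), 8):
            sel = np.zeros(16, dtype=bool)
            sel[list(combo)] = True
            t_perm, _, _ = welch_t(pooled[sel], pooled[~sel])
            total += 1
            count += abs(t_perm) >= abs(t_obs) - 1e-12
        # the permutation null and the t reference distribution are
        # different approximations; they agree only loosely at n=8+8
        assert p == pytest.approx(count / total, abs=0.1)

    def test_too_few_replicates(self):
        with pytest.raises(UndefinedTestError):
            welch_t([1.0], [1, 2, 3])

    def test_zero_variance_both_groups(self):
        with pytest.raises(UndefinedTestError, match="zero variance"):
            welch_t([2, 2, 2], [3, 3, 3])

    def test_null_uniformity_quick(self):
        rng = np.random.default_rng(0)
        hits = 0
        n = 2000
        for _ in range(n):
            _, _, p = welch_t(rng.normal(size=5), rng.normal(size=5))
            hits += p < 0.05
        assert hits / n == pytest.approx(0.05, abs=0.02)


class TestMannWhitney:
    def test_exact_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(2 / 6)

    def test_identical_multisets(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_exact_matches_enumeration_exhaustively(self):
        # every split with pooled size <= 8, on random tie-free data
        rng = np.random.default_rng(9)
        for n in range(2, 9):
            values = rng.normal(size=n)
            for na in range(1, n):
                for combo in itertools.combinations(range(n), na):
                    sel = np.zeros(n, dtype=bool)
                    sel[list(combo)] = True
                    a, b = values[sel], values[~sel]
                    u, p = mann_whitney(a, b)
                    # oracle: direct enumeration of all labelings
                    mu = na * (n - na) / 2
                    obs = abs(u - mu)
                    hits = total = 0
                    for c2 in itertools.combinations(range(n), na):
                        s2 = np.zeros(n, dtype=bool)
                        s2[list(c2)] = True
                        u2 = float(np.sum(values[s2][:, None] > values[~s2][None, :]))
                        total += 1
                        hits += abs(u2 - mu) >= obs - 1e-12
                    assert p == pytest.approx(hits / total, abs=1e-12)

    def test_tied_large_sample_vs_reference(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            a = rng.integers(0, 5, size=12).astype(float)
            b = rng.integers(0, 5, size=15).astype(float)
            u, p = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert u == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_empty_group_errors(self):
        with pytest.raises(UndefinedTestError):
            mann_whitney([], [1.0])


class TestStatColumn:
    def test_pvalues_validated(self):
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            StatColumn("welch_t", "a", "b", pd.Series([1.5]))

    def test_compute_stat_column(self):
        ds = make_dataset(n_probes=5, seed=2)
        treated = tuple(s.sample_id for s in ds.samples if s.dose_level == "Middle")
        controls = tuple(s.sample_id for s in ds.samples if s.dose_level == "Control")
        ga = SampleGroup(name="T", sample_ids=treated, control_sample_ids=())
        gb = SampleGroup(name="C", sample_ids=controls, control_sample_ids=())
        col = compute_stat_column(ds, ga, gb, test="welch_t")
        assert len(col.values) == 5
        for i, probe in enumerate(ds.probes):
            _, _, p = welch_t(ds.columns(treated)[i], ds.columns(controls)[i])
            assert col.values[probe] == pytest.approx(p)


class TestExtractConsistent:
    def make_folds(self, rows):
        return pd.DataFrame(rows, columns=["4 day", "8 day", "15 day", "29 day"]).rename(
            index=lambda i: f"p{i}")

    def test_boundary_half_included(self):
        folds = self.make_folds([[0.5, 0.4, 0.3, 0.5]])
        gs = extract_consistent(folds, 0.5, "down")
        assert gs.members == ("p0",)

    def test_one_failing_time_point_excludes(self):
        folds = self.make_folds([[0.5, 0.6, 0.5, 0.5]])
        assert extract_consistent(folds, 0.5, "down").members == ()

    def test_all_ones_empty_both_directions(self):
        folds = self.make_folds([[1.0, 1.0, 1.0, 1.0]])
        assert extract_consistent(folds, 0.5, "down").members == ()
        assert extract_consistent(folds, 0.5, "up").members == ()

    def test_up_direction_uses_reciprocal(self):
        folds = self.make_folds([[2.0, 2.5, 2.0, 3.0], [2.0, 1.9, 2.0, 3.0]])
        gs = extract_consistent(folds, 0.5, "up")
        assert gs.members == ("p0",)

    def test_missing_time_point_excluded_and_reported(self):
        folds = self.make_folds([[0.4, np.nan, 0.4, 0.4], [0.4, 0.4, 0.4, 0.4]])
        with pytest.warns(UserWarning, match="missing time points"):
            gs = extract_consistent(folds, 0.5, "down")
        assert gs.members == ("p1",)

    def test_invalid_inputs(self):
        folds = self.make_folds([[0.4, 0.4, 0.4, 0.4]])
        with pytest.raises(ValidationError):
            extract_consistent(folds, -1.0, "down")
        with pytest.raises(ValidationError):
            extract_consistent(folds, 0.5, "sideways")


class TestGeneSet:
    def test_duplicates_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            GeneSet("g", ("a", "a"))

    def test_empty_name_rejected(self):
        with pytest.raises(ValidationError):
            GeneSet("", ("a",))


class TestGeneSetAlgebra:
    def test_intersect(self):
        a, b = GeneSet("a", ("x", "y")), GeneSet("b", ("y", "z"))
        assert geneset_algebra(a, b, "intersect").members == ("y",)

    def test_union_with_empty_is_identity(self):
        a, b = GeneSet("a", ("x", "y")), GeneSet("b", ())
        assert geneset_algebra(a, b, "union").members == a.members

    def test_union_ordering(self):
        a, b = GeneSet("a", ("x", "y")), GeneSet("b", ("z", "y", "w"))
        assert geneset_algebra(a, b, "union").members == ("x", "y", "z", "w")

    @given(st.lists(st.sampled_from("abcdefgh"), unique=True),
           st.lists(st.sampled_from("abcdefgh"), unique=True))
    @settings(max_examples=200, deadline=None)
    def test_union_minus_b_subset_of_a(self, la, lb):
        a = GeneSet("a", tuple(la)) if la else GeneSet("a", ())
        b = GeneSet("b", tuple(lb)) if lb else GeneSet("b", ())
        u = geneset_algebra(a, b, "union")
        d = geneset_algebra(u, b, "difference")
        assert set(d.members) <= set(a.members)

    def test_unknown_op(self):
        with pytest.raises(ValidationError):
            geneset_algebra(GeneSet("a", ("x",)), GeneSet("b", ("y",)), "xor")
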