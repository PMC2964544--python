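"""Reliability, correlations, rank tests and clinical groupings."""

import itertools
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promid import (
    cronbach_alpha,
    duration_split,
    edss_grouping,
    known_groups_test,
    relapse_grouping,
    spearman_matrix,
)
from promid.instruments import InstrumentSpec
from promid.psychometrics import (
    EDSS_OUT_OF_PROTOCOL,
    RELAPSE_ZERO,
    DegenerateDataError,
)

from conftest import make_matrix


def alpha_oracle(rows):
    """Spreadsheet-style Cronbach's alpha: explicit sample variances."""
    k = len(rows[0])
    cols = list(zip(*rows))
    item_vars = sum(statistics.variance(c) for c in cols)
    total_var = statistics.variance([sum(r) for r in rows])
    return k / (k - 1) * (1 - item_vars / total_var)


class TestCronbachAlpha:
    def test_hand_variance_oracle(self):
        rows = [[1, 0, 1], [0, 0, 1], [1, 1, 1], [0, 0, 0]]
        spec = InstrumentSpec("tri", "tri", 3, 0, 1)
        res = cronbach_alpha(make_matrix(rows, spec=spec))
        assert res.alpha == pytest.approx(alpha_oracle(rows), abs=1e-12)
        assert res.alpha == pytest.approx(0.75, abs=1e-12)
        assert (res.k, res.n) == (3, 4)

    def test_perfectly_correlated_items(self):
        rows = [[1, 1], [0, 0], [1, 1], [0, 0]]
        spec = InstrumentSpec("two", "two", 2, 0, 1)
        assert cronbach_alpha(make_matrix(rows, spec=spec)).alpha == pytest.approx(1.0)

    def test_zero_covariance_items(self):
        rows = [[1, 1], [1, 0], [0, 1], [0, 0]]
        spec = InstrumentSpec("two", "two", 2, 0, 1)
        assert cronbach_alpha(make_matrix(rows, spec=spec)).alpha == pytest.approx(0.0)

    def test_listwise_deletion_reported(self):
        rows = [[1, 0, 1], [0, 0, 1], [1, 1, 1], [0, 0, 0], [1, None, 1]]
        spec = InstrumentSpec("tri", "tri", 3, 0, 1)
        res = cronbach_alpha(make_matrix(rows, spec=spec))
        assert res.n == 4  # row with the missing item dropped

    def test_degenerate_inputs(self):
        spec = InstrumentSpec("tri", "tri", 3, 0, 1)
        constant = make_matrix([[1, 0, 0], [1, 0, 0], [1, 0, 0]], spec=spec)
        with pytest.raises(DegenerateDataError, match="degenerate"):
            cronbach_alpha(constant)
        tiny = make_matrix([[1, 0, 1], [0, 1, 0]], spec=spec)
        with pytest.raises(DegenerateDataError, match="complete cases"):
            cronbach_alpha(tiny)

    @given(shift=st.integers(1, 3))
    @settings(max_examples=10, deadline=None)
    def test_invariant_to_constant_item_shift(self, shift):
        rows = [[1, 0, 1], [0, 0, 1], [1, 1, 1], [0, 0, 0], [1, 1, 0]]
        spec = InstrumentSpec("wide", "wide", 3, 0, 5)
        base = cronbach_alpha(make_matrix(rows, spec=spec)).alpha
        shifted_rows = [[r[0] + shift, r[1], r[2]] for r in rows]
        shifted = cronbach_alpha(make_matrix(shifted_rows, spec=spec)).alpha
        assert shifted == pytest.approx(base, abs=1e-12)


def rank_oracle(values):
    """Mid-ranks (ties averaged), built from sorting alone."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


class TestSpearman:
    def test_monotone_and_reversed(self):
        df = pd.DataFrame({"x": [1, 2, 3], "y": [10, 20, 30], "z": [3, 2, 1]})
        m = spearman_matrix(df)
        assert m.get("x", "y") == pytest.approx(1.0)
        assert m.get("x", "z") == pytest.approx(-1.0)
        assert np.allclose(np.diag(m.rho), 1.0)

    def test_tied_data_against_rank_oracle(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        rx, ry = rank_oracle(x), rank_oracle(y)
        expected = float(np.corrcoef(rx, ry)[0, 1])
        m = spearman_matrix(pd.DataFrame({"x": x, "y": y}))
        assert m.get("x", "y") == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_n(self):
        df = pd.DataFrame(
            {"x": [1, 2, 3, 4, np.nan], "y": [2, 1, 4, np.nan, 5]}
        )
        m = spearman_matrix(df)
        assert m.n.loc["x", "y"] == 3

    def test_constant_column_undefined_with_warning(self):
        df = pd.DataFrame({"x": [1, 2, 3], "c": [7, 7, 7]})
        with pytest.warns(UserWarning, match="constant"):
            m = spearman_matrix(df)
        assert np.isnan(m.get("x", "c"))

    @given(
        xs=st.lists(st.integers(0, 20), min_size=5, max_size=12, unique=True),
        scale=st.integers(1, 5),
    )
    @settings(max_examples=30, deadline=None)
    def test_invariant_to_monotone_transform(self, xs, scale):
        rng = np.random.default_rng(7)
        y = rng.normal(size=len(xs))
        df1 = pd.DataFrame({"x": xs, "y": y})
        df2 = pd.DataFrame({"x": [np.exp(scale * v / 20) for v in xs], "y": y})
        assert spearman_matrix(df1).get("x", "y") == pytest.approx(
            spearman_matrix(df2).get("x", "y"), abs=1e-12
        )


def mwu_permutation_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(idx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for xi in a for yi in b if xi > yi)

    center = n1 * len(y) / 2
    obs = abs(u_stat(tuple(range(n1))) - center)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(idx) - center) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestKnownGroups:
    def test_separated_groups_exact_p(self):
        res = known_groups_test(
            pd.Series([1, 2, 3, 4, 5, 6.0]),
            pd.Series(["a", "a", "a", "b", "b", "b"]),
        )
        assert res.test == "mann-whitney"
        assert res.statistic == 0
        assert res.pvalue == pytest.approx(0.1)

    def test_identical_groups_central_u(self):
        res = known_groups_test(
            pd.Series([1, 2, 3, 1, 2, 3.0]),
            pd.Series(["a", "a", "a", "b", "b", "b"]),
        )
        assert res.statistic == pytest.approx(4.5)

    def test_three_identical_groups_h_zero(self):
        res = known_groups_test(
            pd.Series([1, 2, 3] * 3, dtype=float),
            pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3),
        )
        assert res.test == "kruskal-wallis"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_group_summaries_mirror_data(self):
        res = known_groups_test(
            pd.Series([1, 3, 10, 12.0]), pd.Series(["a", "a", "b", "b"])
        )
        assert [g.n for g in res.groups] == [2, 2]
        assert res.groups[0].mean == 2 and res.groups[1].mean == 11

    def test_single_group_errors(self):
        with pytest.raises(DegenerateDataError, match="groups"):
            known_groups_test(pd.Series([1.0, 2.0]), pd.Series(["a", "a"]))

    def test_empty_group_dropped_with_warning(self):
        scores = pd.Series([1, 2, 3, 4, np.nan])
        groups = pd.Series(pd.Categorical(
            ["a", "a", "b", "b", "c"], categories=["a", "b", "c"]
        ))
        with pytest.warns(UserWarning, match="empty group"):
            res = known_groups_test(scores, groups)
        assert len(res.groups) == 2

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_exact_p_matches_permutation_enumeration(self, data):
        n1 = data.draw(st.integers(2, 6))
        n2 = data.draw(st.integers(2, 6))
        pool = data.draw(
            st.lists(
                st.integers(0, 1000), min_size=n1 + n2, max_size=n1 + n2, unique=True
            )
        )
        x, y = pool[:n1], pool[n1:]
        res = known_groups_test(
            pd.Series(x + y, dtype=float),
            pd.Series(["a"] * n1 + ["b"] * n2),
        )
        assert res.pvalue == pytest.approx(mwu_permutation_oracle(x, y), abs=1e-9)

    def test_kruskal_consistent_with_mwu_for_two_groups(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0.5, 1, 30)
        scores = pd.Series(np.concatenate([x, y]))
        two = pd.Series(["a"] * 30 + ["b"] * 30)
        mwu_p = known_groups_test(scores, two).pvalue
        from scipy.stats import kruskal

        kw_p = kruskal(x, y).pvalue
        assert kw_p == pytest.approx(mwu_p, abs=0.01)


class TestGroupings:
    @pytest.mark.parametrize(
        "edss, band",
        [
            (0.0, "0-1.5"),
            (1.5, "0-1.5"),
            (2.0, "2-2.5"),
            (3.5, "3-3.5"),
            (4.0, "4-5.5"),
            (5.5, "4-5.5"),
            (6.0, EDSS_OUT_OF_PROTOCOL),
        ],
    )
    def test_edss_band_edges(self, edss, band):
        assert edss_grouping(pd.Series([edss])).iloc[0] == band

    def test_edss_validation(self):
        with pytest.raises(ValueError, match="negative"):
            edss_grouping(pd.Series([-0.5]))
        with pytest.raises(ValueError, match="0-10"):
            edss_grouping(pd.Series([10.5]))

    def test_duration_median_split_ties_below(self):
        labels = duration_split(pd.Series([1, 2, 3, 4.0]))
        assert labels.attrs["median"] == 2.5
        assert labels.tolist() == ["below-median"] * 2 + ["above-median"] * 2
        at_median = duration_split(pd.Series([1, 2, 3.0]))
        assert at_median.iloc[1] == "below-median"

    def test_duration_degenerate_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            duration_split(pd.Series([2.0, 2.0, 2.0]))

    def test_duration_balanced_without_ties(self):
        rng = np.random.default_rng(3)
        d = pd.Series(rng.permutation(np.arange(101, dtype=float)))
        labels = duration_split(d)
        counts = labels.value_counts()
        assert abs(counts["below-median"] - counts["above-median"]) <= 1

    @pytest.mark.parametrize(
        "count, group", [(1, "1"), (2, "2"), (3, "3+"), (4, "3+"), (0, RELAPSE_ZERO)]
    )
    def test_relapse_groups(self, count, group):
        assert relapse_grouping(pd.Series([count])).iloc[0] == group

    def test_relapse_counts_example(self):
        labels = relapse_grouping(pd.Series([1, 2, 2, 3, 4]))
        assert labels.value_counts()[["1", "2", "3+"]].tolist() == [1, 2, 2]

    def test_relapse_validation(self):
        with pytest.raises(ValueError, match="non-integer"):
            relapse_grouping(pd.Series([1.5]))
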