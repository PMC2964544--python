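"""Reliability and validity statistics: Cronbach's alpha, Spearman
correlations, and known-groups comparisons with rank tests.

Known-groups validity asks whether a scale separates clinically distinct
strata: EDSS disability bands (0-1.5, 2-2.5, 3-3.5, 4-5.5), relapse counts in
the previous two years (1 / 2 / 3+), and a median split on disease duration.
Two groups are compared with the Mann-Whitney U test, three or more with the
Kruskal-Wallis one-way analysis of variance; both are run two-sided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import ItemResponseMatrix


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined on the data supplied."""


@dataclass(frozen=True)
class ReliabilityResult:
    """Cronbach's alpha for one instrument, with the cases it used."""

    instrument: str
    alpha: float
    k: int
    n: int


def cronbach_alpha(items: ItemResponseMatrix) -> ReliabilityResult:
    r"""Internal consistency, alpha = k/(k-1) * (1 - sum(var_i) / var_total).

    Variances are sample variances (denominator n-1) over listwise-complete
    rows; ``k`` and ``n`` are reported so the deletion choice is auditable.
    A conventional adequacy threshold is 0.70.
    """
    complete = items.data.dropna()
    k = items.instrument.n_items
    n = len(complete)
    if k < 2:
        raise DegenerateDataError("cronbach_alpha requires at least 2 items")
    if n < 3:
        raise DegenerateDataError(
            f"cronbach_alpha requires >=3 complete cases, got {n}"
        )
    item_var = complete.var(ddof=1)
    total_var = complete.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("degenerate data: zero total-score variance")
    alpha = k / (k - 1) * (1.0 - item_var.sum() / total_var)
    return ReliabilityResult(items.instrument.name, float(alpha), k, n)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Spearman correlations with per-pair sample sizes."""

    names: tuple[str, ...]
    rho: pd.DataFrame
    n: pd.DataFrame

    def get(self, a: str, b: str) -> float:
        return float(self.rho.loc[a, b])


def spearman_matrix(frame: pd.DataFrame) -> CorrelationMatrix:
    """Spearman rank correlations on mid-ranked data, pairwise-complete.

    Ties receive average ranks. A constant column has no rank ordering, so
    its off-diagonal correlations are reported missing with a warning rather
    than as a number.
    """
    names = tuple(frame.columns)
    p = len(names)
    rho = pd.DataFrame(np.eye(p), index=names, columns=names)
    n = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for name in names:
        n.loc[name, name] = int(frame[name].notna().sum())
    for i in range(p):
        for j in range(i + 1, p):
            a, b = names[i], names[j]
            pair = frame[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < 3:
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                warnings.warn(
                    f"spearman_matrix: <3 paired observations for ({a}, {b})"
                )
                continue
            if pair[a].nunique() < 2 or pair[b].nunique() < 2:
                rho.loc[a, b] = rho.loc[b, a] = np.nan
                warnings.warn(
                    f"spearman_matrix: constant column in pair ({a}, {b}); "
                    "rho undefined"
                )
                continue
            r = stats.spearmanr(pair[a], pair[b]).statistic
            rho.loc[a, b] = rho.loc[b, a] = float(r)
    return CorrelationMatrix(names, rho, n)


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class KnownGroupsResult:
    """Rank-test outcome for one grouping variable against one score."""

    grouping: str
    groups: tuple[GroupSummary, ...]
    test: str  # "mann-whitney" | "kruskal-wallis"
    statistic: float
    pvalue: float

    @property
    def group_means(self) -> list[float]:
        return [g.mean for g in self.groups]


def known_groups_test(
    scores: pd.Series,
    groups: pd.Series,
    grouping: str = "",
    exclude: tuple[str, ...] = (),
) -> KnownGroupsResult:
    """Compare score distributions across non-overlapping groups.

    Two groups: Mann-Whitney U, two-sided, exact p when both groups have
    n <= 8 and there are no ties, otherwise the normal approximation with
    tie and continuity corrections. Three or more groups: Kruskal-Wallis H
    with tie correction, chi-square p on (groups - 1) df. Labels listed in
    ``exclude`` (e.g. out-of-protocol strata) are dropped before testing.
    """
    df = pd.DataFrame({"score": scores, "group": groups}).dropna()
    df = df[~df["group"].astype(str).isin([str(e) for e in exclude])]
    if isinstance(groups.dtype, pd.CategoricalDtype):
        order = [g for g in groups.cat.categories if str(g) not in set(map(str, exclude))]
    else:
        order = sorted(df["group"].unique(), key=str)
    samples, summaries = [], []
    for label in order:
        v = df.loc[df["group"] == label, "score"].to_numpy(dtype=float)
        if v.size == 0:
            warnings.warn(f"known_groups_test({grouping}): empty group {label!r} dropped")
            continue
        sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
        summaries.append(GroupSummary(str(label), int(v.size), float(np.mean(v)), sd))
        samples.append(v)
    if len(samples) < 2:
        raise DegenerateDataError(
            f"known_groups_test({grouping}): need >=2 non-empty groups"
        )
    if len(samples) == 2:
        res = stats.mannwhitneyu(
            samples[0], samples[1], alternative="two-sided", method="auto"
        )
        test = "mann-whitney"
    else:
        res = stats.kruskal(*samples)
        test = "kruskal-wallis"
    return KnownGroupsResult(
        grouping=grouping,
        groups=tuple(summaries),
        test=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
    )


EDSS_BANDS = ("0-1.5", "2-2.5", "3-3.5", "4-5.5")
EDSS_OUT_OF_PROTOCOL = ">5.5 (out of protocol)"
EDSS_BAND_UPPER = (1.5, 2.5, 3.5, 5.5)


def edss_grouping(edss: pd.Series) -> pd.Series:
    """Assign EDSS scores to the four disability bands.

    Band edges are inclusive as printed (0-1.5, 2-2.5, 3-3.5, 4-5.5); EDSS
    moves in 0.5 steps so no observable value falls between bands. Scores
    above 5.5 (outside the trial's eligibility window) go to a labelled
    out-of-protocol group that the four-band test excludes.
    """
    edss = pd.Series(edss, dtype=float)
    valid = edss.dropna()
    if (valid < 0).any():
        bad = valid[valid < 0].iloc[0]
        raise ValueError(f"negative EDSS score {bad!r}")
    if (valid > 10).any():
        bad = valid[valid > 10].iloc[0]
        raise ValueError(f"EDSS score {bad!r} above the 0-10 range")
    categories = list(EDSS_BANDS) + [EDSS_OUT_OF_PROTOCOL]
    idx = np.searchsorted(EDSS_BAND_UPPER, edss.to_numpy(dtype=float), side="left")
    labels = pd.Series(
        [categories[i] if not np.isnan(v) else np.nan for i, v in zip(idx, edss)],
        index=edss.index,
    )
    return labels.astype(pd.CategoricalDtype(categories=categories, ordered=True))


DURATION_BELOW = "below-median"
DURATION_ABOVE = "above-median"


def duration_split(duration: pd.Series) -> pd.Series:
    """Median split of disease duration; values at the median go below.

    The returned categorical carries the sample median in ``.attrs["median"]``
    for table headers ("Below median (3.2)").
    """
    duration = pd.Series(duration, dtype=float)
    valid = duration.dropna()
    if (valid < 0).any():
        raise ValueError("negative disease duration")
    med = float(valid.median())
    if valid.nunique() <= 1:
        warnings.warn("duration_split: all durations equal; degenerate split")
    labels = pd.Series(np.nan, index=duration.index, dtype=object)
    labels[duration <= med] = DURATION_BELOW
    labels[duration > med] = DURATION_ABOVE
    out = labels.astype(
        pd.CategoricalDtype(categories=[DURATION_BELOW, DURATION_ABOVE], ordered=True)
    )
    out.attrs["median"] = med
    return out


RELAPSE_GROUPS = ("1", "2", "3+")
RELAPSE_ZERO = "0 (excluded)"


def relapse_grouping(relapses: pd.Series) -> pd.Series:
    """Group relapse counts from the previous two years as 1 / 2 / 3+.

    Zero-relapse subjects (absent under the trial's activity eligibility
    criterion) go to a labelled extra group excluded from the three-group
    test. Non-integer counts are a validation error.
    """
    relapses = pd.Series(relapses, dtype=float)
    valid = relapses.dropna()
    if (valid < 0).any():
        raise ValueError("negative relapse count")
    if (valid != np.round(valid)).any():
        bad = valid[valid != np.round(valid)].iloc[0]
        raise ValueError(f"non-integer relapse count {bad!r}")

    def label(v: float) -> object:
        if np.isnan(v):
            return np.nan
        if v == 0:
            return RELAPSE_ZERO
        if v >= 3:
            return "3+"
        return str(int(v))

    labels = pd.Series([label(v) for v in relapses], index=relapses.index)
    return labels.astype(
        pd.CategoricalDtype(categories=[RELAPSE_ZERO, *RELAPSE_GROUPS], ordered=True)
    )
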