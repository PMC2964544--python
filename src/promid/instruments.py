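"""Instrument definitions, item scoring, descriptive statistics and change scores.

The three sum-scored scales handled here are the PRIMUS QoL scale (22
dichotomous items, total 0-22), the PRIMUS Activities scale (15 three-level
items, total 0-30) and the U-FIS fatigue-impact scale (22 four-level items,
total 0-66). All are scored so that higher totals mean worse outcomes. The
EQ-5D utility anchor is *not* item-scored here; it enters the pipeline as an
externally supplied number per subject and timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .utils import round_half_up

logger = logging.getLogger(__name__)

BASELINE = "baseline"
MONTH12 = "month12"
TIMEPOINTS = (BASELINE, MONTH12)

MISSING_POLICIES = ("complete-case", "half-rule")


class ScoringError(ValueError):
    """Raised for out-of-range responses or malformed item matrices."""


@dataclass(frozen=True)
class InstrumentSpec:
    """Static definition of a sum-scored scale.

    Items share a common response range ``[item_min, item_max]``; the total
    is the plain item sum, so ``score_min = n_items * item_min`` and
    ``score_max = n_items * item_max`` by construction.
    """

    name: str
    label: str
    n_items: int
    item_min: int
    item_max: int
    higher_is_worse: bool = True

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be positive")
        if self.item_max <= self.item_min:
            raise ValueError("item_max must exceed item_min")

    @property
    def score_min(self) -> int:
        return self.n_items * self.item_min

    @property
    def score_max(self) -> int:
        return self.n_items * self.item_max

    @property
    def n_levels(self) -> int:
        return self.item_max - self.item_min + 1

    def item_columns(self) -> list[str]:
        return [f"{self.name}_item_{i:02d}" for i in range(1, self.n_items + 1)]


PRIMUS_QOL = InstrumentSpec("primus_qol", "PRIMUS QoL", n_items=22, item_min=0, item_max=1)
PRIMUS_ACTIVITIES = InstrumentSpec(
    "primus_activities", "PRIMUS Activities", n_items=15, item_min=0, item_max=2
)
UFIS = InstrumentSpec("ufis", "U-FIS", n_items=22, item_min=0, item_max=3)

INSTRUMENTS: dict[str, InstrumentSpec] = {
    s.name: s for s in (PRIMUS_QOL, PRIMUS_ACTIVITIES, UFIS)
}


def get_instrument(name: str) -> InstrumentSpec:
    try:
        return INSTRUMENTS[name]
    except KeyError:
        raise KeyError(
            f"unknown instrument {name!r}; known: {sorted(INSTRUMENTS)}"
        ) from None


@dataclass
class ItemResponseMatrix:
    """Subjects x items responses for one instrument at one timepoint.

    ``data`` is a float DataFrame indexed by subject id with one column per
    item; missing responses are NaN. Validation rejects duplicate subject
    ids, a wrong column count and out-of-range response levels.
    """

    instrument: InstrumentSpec
    timepoint: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ScoringError(f"duplicated subject id {dup!r} at {self.timepoint}")
        if self.data.shape[1] != self.instrument.n_items:
            raise ScoringError(
                f"{self.instrument.name}: expected {self.instrument.n_items} item "
                f"columns, got {self.data.shape[1]}"
            )
        self.data = self.data.astype(float)
        values = self.data.to_numpy()
        bad = np.zeros(values.shape, dtype=bool)
        with np.errstate(invalid="ignore"):
            observed = ~np.isnan(values)
            bad[observed] = (
                (values[observed] < self.instrument.item_min)
                | (values[observed] > self.instrument.item_max)
                | (values[observed] != np.round(values[observed]))
            )
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ScoringError(
                f"{self.instrument.name}: subject {self.data.index[i]!r}, item "
                f"{self.data.columns[j]!r} has response {values[i, j]!r} outside "
                f"[{self.instrument.item_min}, {self.instrument.item_max}]"
            )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


def score_totals(items: ItemResponseMatrix, policy: str = "complete-case") -> pd.Series:
    """Sum item responses into scale totals.

    Under the default ``"complete-case"`` policy any missing item leaves the
    total missing. Under ``"half-rule"`` a total is prorated when more than
    half the items were answered: mean of answered items times the item
    count, rounded half-up to an integer.
    """
    if policy not in MISSING_POLICIES:
        raise ValueError(f"unknown missing-item policy {policy!r}")
    values = items.data.to_numpy()
    answered = ~np.isnan(values)
    n_answered = answered.sum(axis=1)
    raw_sum = np.nansum(values, axis=1)
    spec = items.instrument
    if policy == "complete-case":
        total = np.where(n_answered == spec.n_items, raw_sum, np.nan)
    else:
        with np.errstate(invalid="ignore"):
            prorated = raw_sum / n_answered * spec.n_items
        total = np.array(
            [
                round_half_up(p, 0) if n > spec.n_items / 2 else np.nan
                for p, n in zip(prorated, n_answered)
            ]
        )
    return pd.Series(total, index=items.data.index, name=spec.name)


@dataclass(frozen=True)
class DescriptiveStats:
    """Distributional summary of one score column, including floor/ceiling."""

    n: int
    mean: float
    sd: float
    median: float
    iqr_low: float
    iqr_high: float
    pct_floor: float
    pct_ceiling: float

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "iqr_low": self.iqr_low,
            "iqr_high": self.iqr_high,
            "pct_floor": self.pct_floor,
            "pct_ceiling": self.pct_ceiling,
        }


def descriptive_stats(
    scores: Iterable[float],
    score_min: float | None = None,
    score_max: float | None = None,
) -> DescriptiveStats:
    """Mean/SD/median/IQR plus percent at the scale floor and ceiling.

    SD is the sample standard deviation (denominator n-1); percentiles use
    linear interpolation between closest ranks. Floor/ceiling percentages are
    computed against the supplied theoretical bounds and are NaN when the
    corresponding bound is unknown.
    """
    v = np.asarray(pd.Series(scores, dtype=float).dropna())
    if v.size == 0:
        raise ValueError("descriptive_stats requires at least one non-missing score")
    n = int(v.size)
    sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])  # linear interpolation
    pct_floor = (
        float(np.mean(v == score_min) * 100) if score_min is not None else float("nan")
    )
    pct_ceiling = (
        float(np.mean(v == score_max) * 100) if score_max is not None else float("nan")
    )
    return DescriptiveStats(
        n=n,
        mean=float(np.mean(v)),
        sd=sd,
        median=float(q50),
        iqr_low=float(q25),
        iqr_high=float(q75),
        pct_floor=pct_floor,
        pct_ceiling=pct_ceiling,
    )


def change_scores(baseline: pd.Series, followup: pd.Series) -> pd.Series:
    """Follow-up minus baseline per subject, missing-propagating.

    Improvement on a higher-is-worse scale is therefore a *negative* change.
    Subjects present at only one timepoint are dropped with a logged count;
    duplicated subject ids are an error.
    """
    for name, s in (("baseline", baseline), ("followup", followup)):
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise ScoringError(f"duplicated subject id {dup!r} in {name} scores")
    common = baseline.index.intersection(followup.index)
    dropped = (len(baseline) - len(common)) + (len(followup) - len(common))
    if dropped:
        logger.info(
            "change_scores(%s): %d subject(s) present at only one timepoint excluded",
            baseline.name,
            dropped,
        )
    change = followup.loc[common].astype(float) - baseline.loc[common].astype(float)
    change.name = f"{baseline.name}_change" if baseline.name else "change"
    return change


class ScoreTable:
    """Wide per-subject table of scale totals, change scores and covariates.

    One row per subject; columns ``<instrument>_baseline``,
    ``<instrument>_month12`` and ``<instrument>_change`` per instrument, plus
    whatever covariate columns were supplied (EDSS, relapse count, disease
    duration, EQ-5D utility at both timepoints, MSFC sub-scores). An
    ``eq5d_change`` column is derived when both utility columns are present.
    """

    def __init__(self, frame: pd.DataFrame, exclusions: dict[str, int] | None = None):
        self.frame = frame
        self.exclusions = exclusions or {}

    @classmethod
    def build(
        cls,
        items: Mapping[str, Mapping[str, ItemResponseMatrix]],
        covariates: pd.DataFrame | None = None,
        policy: str = "complete-case",
    ) -> "ScoreTable":
        columns: dict[str, pd.Series] = {}
        exclusions: dict[str, int] = {}
        index = pd.Index([], name="subject_id")
        for name, by_tp in items.items():
            for tp, matrix in by_tp.items():
                columns[f"{name}_{tp}"] = score_totals(matrix, policy=policy)
                index = index.union(matrix.data.index)
        if covariates is not None:
            if covariates.index.has_duplicates:
                raise ScoringError("duplicated subject id in covariate table")
            index = index.union(covariates.index)
        frame = pd.DataFrame(index=index)
        frame.index.name = "subject_id"
        for col, series in columns.items():
            frame[col] = series.reindex(index)
        for name, by_tp in items.items():
            b, f = f"{name}_{BASELINE}", f"{name}_{MONTH12}"
            if b in frame.columns and f in frame.columns:
                n_one_tp = int(
                    (frame[b].notna() ^ frame[f].notna()).sum()
                )
                exclusions[f"{name}_single_timepoint"] = n_one_tp
                frame[f"{name}_change"] = frame[f] - frame[b]
        if covariates is not None:
            for col in covariates.columns:
                frame[col] = covariates[col].reindex(index)
            if {"eq5d_baseline", "eq5d_month12"} <= set(frame.columns):
                frame["eq5d_change"] = frame["eq5d_month12"] - frame["eq5d_baseline"]
        return cls(frame, exclusions)

    def scores(self, instrument: str, timepoint: str = BASELINE) -> pd.Series:
        return self.frame[f"{instrument}_{timepoint}"]

    def change(self, instrument: str) -> pd.Series:
        return self.frame[f"{instrument}_change"]
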