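"""The validation model and its fitted results.

``PROValidation`` is constructed from item-level responses plus a covariate
table (or directly from a synthetic cohort or the CSV dialects); ``fit()``
runs the full battery — scoring, descriptives with floor/ceiling effects,
Cronbach's alpha, Spearman convergent-validity correlations, known-groups
rank tests and the anchor/distribution responder-definition estimates — and
returns a ``PROValidationResults`` object that renders the four standard
report tables and a plain-text summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as _io
from .instruments import (
    BASELINE,
    INSTRUMENTS,
    MONTH12,
    DescriptiveStats,
    ItemResponseMatrix,
    ScoreTable,
    descriptive_stats,
)
from .psychometrics import (
    EDSS_OUT_OF_PROTOCOL,
    RELAPSE_ZERO,
    CorrelationMatrix,
    KnownGroupsResult,
    ReliabilityResult,
    cronbach_alpha,
    duration_split,
    edss_grouping,
    known_groups_test,
    relapse_grouping,
)
from .responder import AnchorSpec, RDEstimateSet, estimate_rd
from .simulate import SyntheticCohort
from .utils import format_p, round_half_up

logger = logging.getLogger(__name__)

_MSFC_COLUMNS = ("msfc_walk", "msfc_peg", "msfc_pasat", "msfc_total")


class PROValidation:
    """Psychometric validation model for sum-scored PRO instruments.

    Parameters
    ----------
    items
        Mapping ``instrument name -> timepoint -> ItemResponseMatrix``.
    covariates
        Per-subject clinical table indexed by subject id (EDSS, relapse
        count, disease duration, EQ-5D utility at both timepoints, MSFC
        sub-scores as already-computed numbers). Optional columns are simply
        skipped by the analyses that need them.
    anchor
        Anchor definition for the responder analysis; defaults to the EQ-5D
        utility with its published responder definition of 0.074.
    missing_policy
        "complete-case" (default) or "half-rule" item-missingness scoring.
    es_levels
        Effect sizes whose equivalent change scores are tabulated.
    """

    def __init__(
        self,
        items: Mapping[str, Mapping[str, ItemResponseMatrix]],
        covariates: pd.DataFrame | None = None,
        anchor: AnchorSpec | None = None,
        missing_policy: str = "complete-case",
        es_levels: tuple[float, ...] = (0.3, 0.5),
    ):
        self.items = dict(items)
        self.covariates = covariates
        self.anchor = anchor or AnchorSpec()
        self.missing_policy = missing_policy
        self.es_levels = tuple(es_levels)

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, **kwargs) -> "PROValidation":
        return cls(cohort.items, cohort.covariates, **kwargs)

    @classmethod
    def from_csv(
        cls, items_csv: str | Path, covariates_csv: str | Path | None = None, **kwargs
    ) -> "PROValidation":
        items = _io.read_items_csv(items_csv)
        cov = _io.read_covariates_csv(covariates_csv) if covariates_csv else None
        return cls(items, cov, **kwargs)

    def fit(self) -> "PROValidationResults":
        scores = ScoreTable.build(self.items, self.covariates, self.missing_policy)
        frame = scores.frame

        descriptives: dict[tuple[str, str], DescriptiveStats] = {}
        for name in self.items:
            spec = INSTRUMENTS[name]
            for tp in (BASELINE, MONTH12):
                col = f"{name}_{tp}"
                if col in frame and frame[col].notna().any():
                    descriptives[(name, tp)] = descriptive_stats(
                        frame[col], spec.score_min, spec.score_max
                    )
        for tp, col in ((BASELINE, "eq5d_baseline"), (MONTH12, "eq5d_month12")):
            if col in frame and frame[col].notna().any():
                lo, hi = self.anchor.score_range
                descriptives[(self.anchor.name, tp)] = descriptive_stats(frame[col], lo, hi)

        reliability = {
            name: cronbach_alpha(by_tp[BASELINE])
            for name, by_tp in self.items.items()
            if BASELINE in by_tp
        }

        corr_cols = [f"{name}_{BASELINE}" for name in self.items]
        corr_names = list(self.items)
        for extra in (*_MSFC_COLUMNS, "edss", "eq5d_baseline"):
            if extra in frame.columns:
                corr_cols.append(extra)
                corr_names.append(extra)
        corr_frame = frame[corr_cols].copy()
        corr_frame.columns = corr_names
        correlations = (
            _safe_spearman(corr_frame) if len(corr_names) >= 2 else None
        )

        known_groups: dict[tuple[str, str], KnownGroupsResult] = {}
        groupings: dict[str, tuple[pd.Series, tuple[str, ...]]] = {}
        if "edss" in frame.columns:
            groupings["edss"] = (edss_grouping(frame["edss"]), (EDSS_OUT_OF_PROTOCOL,))
        if "relapses_2yr" in frame.columns:
            groupings["relapses"] = (relapse_grouping(frame["relapses_2yr"]), (RELAPSE_ZERO,))
        if "duration_yrs" in frame.columns:
            groupings["duration"] = (duration_split(frame["duration_yrs"]), ())
        grouping_meta = {
            name: labels.attrs.copy() for name, (labels, _) in groupings.items()
        }
        for gname, (labels, exclude) in groupings.items():
            for name in self.items:
                col = f"{name}_{BASELINE}"
                known_groups[(gname, name)] = known_groups_test(
                    frame[col], labels, grouping=f"{gname}/{name}", exclude=exclude
                )

        rd: dict[str, RDEstimateSet] = {}
        anchor_change = frame.get("eq5d_change")
        for name in self.items:
            change_col = f"{name}_change"
            if change_col not in frame.columns or anchor_change is None:
                logger.warning("responder analysis skipped for %s (no change/anchor data)", name)
                continue
            sd_baseline = float(frame[f"{name}_{BASELINE}"].std(ddof=1))
            rd[name] = estimate_rd(
                instrument=name,
                target_change=frame[change_col],
                anchor_change=anchor_change,
                sd_baseline=sd_baseline,
                alpha=reliability[name].alpha,
                anchor=self.anchor,
                es_levels=self.es_levels,
            )

        return PROValidationResults(
            model=self,
            score_table=scores,
            descriptives=descriptives,
            reliability=reliability,
            correlations=correlations,
            known_groups=known_groups,
            grouping_meta=grouping_meta,
            rd=rd,
        )


def _safe_spearman(frame: pd.DataFrame) -> CorrelationMatrix:
    from .psychometrics import spearman_matrix

    return spearman_matrix(frame)


@dataclass
class PROValidationResults:
    """Fitted validation battery with table renderers.

    Attributes mirror the report blocks: ``descriptives`` (per instrument
    and timepoint), ``reliability`` (Cronbach's alpha), ``correlations``
    (Spearman matrix), ``known_groups`` (rank tests keyed by grouping and
    instrument) and ``rd`` (responder-definition sets per instrument).
    """

    model: PROValidation
    score_table: ScoreTable
    descriptives: dict[tuple[str, str], DescriptiveStats]
    reliability: dict[str, ReliabilityResult]
    correlations: CorrelationMatrix | None
    known_groups: dict[tuple[str, str], KnownGroupsResult]
    grouping_meta: dict[str, dict]
    rd: dict[str, RDEstimateSet]

    # ---------- machine-readable frames ----------

    def descriptives_frame(self) -> pd.DataFrame:
        rows = []
        for (name, tp), d in self.descriptives.items():
            rows.append({"instrument": name, "timepoint": tp, **d.as_dict()})
        return pd.DataFrame(rows)

    def correlations_frame(self) -> pd.DataFrame:
        if self.correlations is None:
            return pd.DataFrame(columns=["var1", "var2", "rho", "n"])
        rows = []
        names = self.correlations.names
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "rho": float(self.correlations.rho.loc[a, b]),
                        "n": int(self.correlations.n.loc[a, b]),
                    }
                )
        return pd.DataFrame(rows)

    def known_groups_frame(self) -> pd.DataFrame:
        rows = []
        for (gname, iname), res in self.known_groups.items():
            for g in res.groups:
                rows.append(
                    {
                        "grouping": gname,
                        "group": g.label,
                        "instrument": iname,
                        "n": g.n,
                        "mean": g.mean,
                        "sd": g.sd,
                        "test": res.test,
                        "statistic": res.statistic,
                        "p": res.pvalue,
                    }
                )
        return pd.DataFrame(rows)

    def rd_frame(self) -> pd.DataFrame:
        rows = []
        for name, est in self.rd.items():
            for label, stratum in (
                ("anchor_improve", est.anchor_improve),
                ("anchor_deteriorate", est.anchor_deteriorate),
                ("anchor_stable", est.anchor_stable),
            ):
                rows.append(
                    {
                        "instrument": name,
                        "estimator": label,
                        "n": stratum.n,
                        "value": stratum.mean if stratum.available else np.nan,
                    }
                )
            rows.append(
                {"instrument": name, "estimator": "sem", "n": est.n_distribution,
                 "value": est.sem_estimate}
            )
            for es, change in est.es_changes.items():
                rows.append(
                    {"instrument": name, "estimator": f"es{es:.2f}_change",
                     "n": est.n_distribution, "value": change}
                )
            lo, hi = est.final_range
            rows.append({"instrument": name, "estimator": "final_range_low",
                         "n": np.nan, "value": lo})
            rows.append({"instrument": name, "estimator": "final_range_high",
                         "n": np.nan, "value": hi})
        return pd.DataFrame(rows)

    # ---------- human-readable summary ----------

    def summary(self) -> str:
        lines: list[str] = []
        add = lines.append
        add("Patient-reported outcome validation summary")
        add("=" * 44)
        add("")
        add("Descriptive statistics (floor/ceiling are % at scale min/max)")
        for (name, tp), d in self.descriptives.items():
            label = INSTRUMENTS[name].label if name in INSTRUMENTS else name
            add(
                f"  {label:<18} {tp:<9} n={d.n:<5d} mean (SD) "
                f"{round_half_up(d.mean):>5.1f} ({round_half_up(d.sd):.1f})  "
                f"median (IQR) {round_half_up(d.median):.1f} "
                f"({round_half_up(d.iqr_low):.1f} - {round_half_up(d.iqr_high):.1f})  "
                f"floor {round_half_up(d.pct_floor):.1f}%  ceiling {round_half_up(d.pct_ceiling):.1f}%"
            )
        add("")
        add("Internal consistency (Cronbach's alpha; >=0.70 adequate)")
        for name, r in self.reliability.items():
            add(f"  {INSTRUMENTS[name].label:<18} alpha={r.alpha:.2f}  k={r.k}  n={r.n}")
        if self.correlations is not None:
            add("")
            add("Convergent validity (Spearman rho, baseline, pairwise-complete)")
            names = self.correlations.names
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    rho = self.correlations.rho.loc[a, b]
                    rho_s = "NA" if np.isnan(rho) else f"{rho:+.2f}"
                    add(f"  {a:<22} vs {b:<16} rho={rho_s}  n={int(self.correlations.n.loc[a, b])}")
        if self.known_groups:
            add("")
            add("Known-groups validity (baseline scores)")
            seen = []
            for (gname, iname), res in self.known_groups.items():
                if gname not in seen:
                    seen.append(gname)
                    extra = ""
                    med = self.grouping_meta.get(gname, {}).get("median")
                    if med is not None:
                        extra = f" (median {round_half_up(med):.1f})"
                    add(f"  -- {gname}{extra} --")
                cells = "  ".join(
                    f"{g.label}: n={g.n} mean={round_half_up(g.mean):.1f} "
                    f"(SD {round_half_up(g.sd):.1f})"
                    for g in res.groups
                )
                add(f"  {INSTRUMENTS[iname].label:<18} {cells}")
                add(f"  {'':<18} {res.test}: p {format_p(res.pvalue)}")
        if self.rd:
            add("")
            add("Responder-definition estimates (change = month12 - baseline;")
            add("negative change is improvement on these higher-is-worse scales)")
            for name, est in self.rd.items():
                add(f"  -- {INSTRUMENTS[name].label} --")
                for label, s in (
                    ("anchor: EQ-5D RD improvement", est.anchor_improve),
                    ("anchor: EQ-5D RD deterioration", est.anchor_deteriorate),
                    ("anchor: EQ-5D stable (descriptive)", est.anchor_stable),
                ):
                    val = "unavailable" if not s.available else f"{round_half_up(s.mean):.1f}"
                    add(f"    {label:<34} n={s.n:<5d} mean change {val}")
                add(
                    f"    {'SEM (s1*sqrt(1-alpha))':<34} n={est.n_distribution:<5d} "
                    f"{round_half_up(est.sem_estimate):.1f}"
                )
                for es, change in est.es_changes.items():
                    add(
                        f"    {f'change for {es:.2f} ES':<34} n={est.n_distribution:<5d} "
                        f"{round_half_up(change):.1f}"
                    )
                lo, hi = est.final_range
                add(f"    triangulated RD range: {lo:.1f} - {hi:.1f}")
        add("")
        return "\n".join(lines)

    def save_tables(self, outdir: str | Path) -> dict[str, Path]:
        """Write the four report tables (full precision) and report.txt."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "table2_descriptives": outdir / "table2_descriptives.csv",
            "table3_correlations": outdir / "table3_correlations.csv",
            "table4_known_groups": outdir / "table4_known_groups.csv",
            "table5_rd": outdir / "table5_rd.csv",
            "report": outdir / "report.txt",
        }
        self.descriptives_frame().to_csv(paths["table2_descriptives"], index=False)
        self.correlations_frame().to_csv(paths["table3_correlations"], index=False)
        self.known_groups_frame().to_csv(paths["table4_known_groups"], index=False)
        self.rd_frame().to_csv(paths["table5_rd"], index=False)
        paths["report"].write_text(self.summary())
        return paths


def run_validation(
    items: Mapping[str, Mapping[str, ItemResponseMatrix]],
    covariates: pd.DataFrame | None = None,
    **kwargs,
) -> PROValidationResults:
    """Convenience wrapper: build the model and fit it in one call."""
    return PROValidation(items, covariates, **kwargs).fit()


def run_rd(
    results: PROValidationResults | None = None,
    overrides: Mapping[str, Mapping[str, float]] | None = None,
    es_levels: tuple[float, ...] = (0.3, 0.5),
) -> pd.DataFrame:
    """Responder-definition block, optionally from printed inputs alone.

    ``overrides`` maps instrument name to ``{"sd": ..., "alpha": ...}``;
    instruments listed there get distribution-based estimates recomputed
    from those externally supplied values (e.g. a published table) instead
    of — or in the absence of — raw data. Returns the RD block as a frame.
    """
    from .responder import distribution_estimates

    rows = []
    if results is not None:
        frame = results.rd_frame()
        if overrides:
            frame = frame[~frame["instrument"].isin(overrides)]
        rows.append(frame)
    for name, ov in (overrides or {}).items():
        dist = distribution_estimates(ov["sd"], ov["alpha"], es_levels)
        block = [{"instrument": name, "estimator": "sem", "n": np.nan, "value": dist["sem"]}]
        for es in es_levels:
            block.append(
                {"instrument": name, "estimator": f"es{es:.2f}_change",
                 "n": np.nan, "value": dist[f"es{es:.2f}"]}
            )
        rows.append(pd.DataFrame(block))
    if not rows:
        raise ValueError("run_rd needs fitted results or overrides")
    return pd.concat(rows, ignore_index=True)
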