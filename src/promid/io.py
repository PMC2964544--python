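"""Reading and writing the pipeline's CSV dialects.

Item-level CSV: one row per subject x timepoint, columns ``subject_id``,
``timepoint`` and ``<instrument>_item_01..N`` for every instrument present;
missing cells are empty. Covariate CSV: one row per subject with
``subject_id``, clinical covariates and the EQ-5D utility at both
timepoints.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .instruments import INSTRUMENTS, TIMEPOINTS, ItemResponseMatrix, ScoringError
from .simulate import SyntheticCohort

COVARIATE_COLUMNS = (
    "edss",
    "relapses_2yr",
    "duration_yrs",
    "eq5d_baseline",
    "eq5d_month12",
)


def write_items_csv(
    items: Mapping[str, Mapping[str, ItemResponseMatrix]], path: str | Path
) -> None:
    rows = []
    for tp in TIMEPOINTS:
        frames = [
            by_tp[tp].data for by_tp in items.values() if tp in by_tp
        ]
        if not frames:
            continue
        wide = pd.concat(frames, axis=1)
        wide.insert(0, "timepoint", tp)
        rows.append(wide.reset_index())
    out = pd.concat(rows, axis=0, ignore_index=True)
    out.to_csv(path, index=False, float_format="%g")


def read_items_csv(
    path: str | Path, instruments: tuple[str, ...] | None = None
) -> dict[str, dict[str, ItemResponseMatrix]]:
    df = pd.read_csv(path)
    required = {"subject_id", "timepoint"}
    missing = required - set(df.columns)
    if missing:
        raise ScoringError(f"item CSV missing columns: {sorted(missing)}")
    present = {
        name: spec
        for name, spec in INSTRUMENTS.items()
        if (instruments is None or name in instruments)
        and set(spec.item_columns()) <= set(df.columns)
    }
    if not present:
        raise ScoringError("item CSV contains no complete instrument column block")
    out: dict[str, dict[str, ItemResponseMatrix]] = {}
    for name, spec in present.items():
        out[name] = {}
        for tp, chunk in df.groupby("timepoint"):
            if tp not in TIMEPOINTS:
                raise ScoringError(f"unknown timepoint label {tp!r}")
            data = chunk.set_index("subject_id")[spec.item_columns()]
            out[name][str(tp)] = ItemResponseMatrix(spec, str(tp), data)
    return out


def write_covariates_csv(covariates: pd.DataFrame, path: str | Path) -> None:
    covariates.reset_index().to_csv(path, index=False, float_format="%g")


def read_covariates_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ScoringError("covariate CSV missing subject_id column")
    return df.set_index("subject_id")


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated cohort in the pipeline's input dialect.

    Ground truth goes to its own file; the analysis inputs never include it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "items": outdir / "items.csv",
        "covariates": outdir / "covariates.csv",
        "ground_truth": outdir / "ground_truth.csv",
    }
    write_items_csv(cohort.items, paths["items"])
    write_covariates_csv(cohort.covariates, paths["covariates"])
    cohort.ground_truth.reset_index().to_csv(paths["ground_truth"], index=False)
    return paths
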