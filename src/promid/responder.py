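"""Responder-definition (minimal important difference) estimation.

Two families of estimators are triangulated per scale:

* **Anchor-based** — mean target-scale change among subjects whose EQ-5D
  utility changed by 1 to 1.5 times the utility's published responder
  definition of 0.074 (i.e. a change of 0.074-0.111, in either direction).
  Subjects whose utility change is exactly zero form a descriptive "stable"
  stratum that is reported but not triangulated.
* **Distribution-based** — the standard error of measurement
  SEM = s1 * sqrt(1 - r) (baseline SD s1, internal consistency r), and the
  change scores equivalent to effect sizes of 0.30 and 0.50 of the baseline
  SD. The 0.50-ES change is identically the half-SD criterion.

The final responder-definition range per scale is the min-max of the
absolute values of the five primary estimates, after rounding to the one
decimal place at which such tables are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .utils import round_half_up

_EPS = 1e-9  # guards inclusive band edges against float representation noise


@dataclass(frozen=True)
class AnchorSpec:
    """External anchor with a published responder definition.

    Defaults describe the EQ-5D utility: higher is better, published RD
    0.074, anchor band 1-1.5 times the RD. ``score_range`` is the utility
    support used for floor/ceiling summaries (clip bounds of the synthetic
    generator; the theoretical minimum depends on the value set, which is
    out of scope here).
    """

    name: str = "eq5d"
    published_rd: float = 0.074
    band_multipliers: tuple[float, float] = (1.0, 1.5)
    higher_is_better: bool = True
    score_range: tuple[float, float] = (-0.2, 1.0)

    def __post_init__(self) -> None:
        if self.published_rd <= 0:
            raise ValueError("published_rd must be positive")
        lo, hi = self.band_multipliers
        if not (0 < lo <= hi):
            raise ValueError("band_multipliers must satisfy 0 < low <= high")

    @property
    def band(self) -> tuple[float, float]:
        lo, hi = self.band_multipliers
        return (self.published_rd * lo, self.published_rd * hi)


@dataclass(frozen=True)
class StratumEstimate:
    """Sample size and mean change in one anchor stratum.

    ``mean`` is None when the stratum is empty ("unavailable", never zero).
    """

    n: int
    mean: float | None

    @property
    def available(self) -> bool:
        return self.n > 0 and self.mean is not None


@dataclass(frozen=True)
class RDEstimateSet:
    """The five responder-definition estimates for one scale, plus range.

    ``final_range`` spans the absolute values of the available estimates
    among {anchor improvement, anchor deterioration, SEM, 0.30-ES change,
    0.50-ES change}, each rounded to 1 decimal as tabulated. The stable
    stratum is descriptive only.
    """

    instrument: str
    anchor_improve: StratumEstimate
    anchor_deteriorate: StratumEstimate
    anchor_stable: StratumEstimate
    sem_estimate: float
    es_changes: dict[float, float]
    n_distribution: int
    final_range: tuple[float, float]


def select_anchor_strata(
    anchor_change: pd.Series, spec: AnchorSpec | None = None
) -> dict[str, pd.Index]:
    """Partition subjects into improved / deteriorated / stable strata.

    Improvement means anchor change inside ``[+band_low, +band_high]`` when
    higher anchor values are better (the negated interval otherwise);
    deterioration is the mirrored interval; stable is exactly zero change.
    Band endpoints are inclusive. Subjects outside all three sets (including
    missing anchor changes) belong to no stratum.
    """
    spec = spec or AnchorSpec()
    change = pd.Series(anchor_change, dtype=float)
    lo, hi = spec.band
    sign = 1.0 if spec.higher_is_better else -1.0
    signed = sign * change
    improved = (signed >= lo - _EPS) & (signed <= hi + _EPS)
    deteriorated = (-signed >= lo - _EPS) & (-signed <= hi + _EPS)
    stable = signed.abs() <= _EPS
    strata = {
        "improved": change.index[improved.fillna(False)],
        "deteriorated": change.index[deteriorated.fillna(False)],
        "stable": change.index[stable.fillna(False)],
    }
    for name, idx in strata.items():
        if len(idx) == 0:
            warnings.warn(f"select_anchor_strata: empty {name!r} stratum")
    return strata


def anchor_rd(
    target_change: pd.Series, strata: dict[str, pd.Index]
) -> dict[str, StratumEstimate]:
    """Mean target-scale change per anchor stratum.

    Missing target changes drop out of both n and the mean; an empty (or
    all-missing) stratum yields an unavailable estimate with a warning.
    """
    target_change = pd.Series(target_change, dtype=float)
    out: dict[str, StratumEstimate] = {}
    for name, idx in strata.items():
        values = target_change.reindex(idx).dropna()
        if len(values) == 0:
            warnings.warn(f"anchor_rd: {name!r} stratum estimate unavailable")
            out[name] = StratumEstimate(n=0, mean=None)
        else:
            out[name] = StratumEstimate(n=int(len(values)), mean=float(values.mean()))
    return out


def sem(sd_baseline: float, alpha: float) -> float:
    """Standard error of measurement, s1 * sqrt(1 - r)."""
    if sd_baseline < 0:
        raise ValueError("sd_baseline must be non-negative")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"reliability must lie in [0, 1], got {alpha!r}")
    return float(sd_baseline) * math.sqrt(1.0 - float(alpha))


def es_equivalent_change(sd_baseline: float, es: float) -> float:
    """Change score producing a given group effect size: es * s1.

    At es = 0.5 this is exactly half the baseline SD (the half-SD rule).
    """
    if sd_baseline < 0:
        raise ValueError("sd_baseline must be non-negative")
    if es < 0:
        raise ValueError("effect size must be non-negative")
    return float(es) * float(sd_baseline)


def rd_summary(estimates: dict[str, float | None]) -> tuple[float, float]:
    """Triangulate the final RD range over the available estimates.

    Takes absolute values (anchor improvements are negative on a
    higher-is-worse scale), rounds each to 1 decimal as tabulated, then
    returns (min, max).
    """
    rounded = [
        round_half_up(abs(v), 1)
        for v in estimates.values()
        if v is not None and not math.isnan(v)
    ]
    if not rounded:
        raise ValueError("rd_summary: no available estimates")
    return (min(rounded), max(rounded))


def distribution_estimates(
    sd_baseline: float,
    alpha: float,
    es_levels: tuple[float, ...] = (0.3, 0.5),
) -> dict[str, float]:
    """SEM and ES-equivalent change scores from printed or computed inputs."""
    out = {"sem": sem(sd_baseline, alpha)}
    for es in es_levels:
        out[f"es{es:.2f}"] = es_equivalent_change(sd_baseline, es)
    return out


def estimate_rd(
    instrument: str,
    target_change: pd.Series,
    anchor_change: pd.Series,
    sd_baseline: float,
    alpha: float,
    anchor: AnchorSpec | None = None,
    es_levels: tuple[float, ...] = (0.3, 0.5),
    n_distribution: int | None = None,
) -> RDEstimateSet:
    """Full anchor + distribution responder-definition set for one scale.

    ``sd_baseline`` is the baseline SD of all baseline completers (not the
    change-score subsample) and ``alpha`` the baseline internal consistency.
    ``n_distribution`` is the sample size to report next to the
    distribution-based rows (the number of change-score completers).
    """
    anchor = anchor or AnchorSpec()
    strata = select_anchor_strata(anchor_change, anchor)
    anchor_est = anchor_rd(target_change, strata)
    dist = distribution_estimates(sd_baseline, alpha, es_levels)
    primary: dict[str, float | None] = {
        "anchor_improve": anchor_est["improved"].mean,
        "anchor_deteriorate": anchor_est["deteriorated"].mean,
        "sem": dist["sem"],
    }
    for es in es_levels:
        primary[f"es{es:.2f}"] = dist[f"es{es:.2f}"]
    if n_distribution is None:
        n_distribution = int(pd.Series(target_change, dtype=float).notna().sum())
    return RDEstimateSet(
        instrument=instrument,
        anchor_improve=anchor_est["improved"],
        anchor_deteriorate=anchor_est["deteriorated"],
        anchor_stable=anchor_est["stable"],
        sem_estimate=dist["sem"],
        es_changes={es: dist[f"es{es:.2f}"] for es in es_levels},
        n_distribution=n_distribution,
        final_range=rd_summary(primary),
    )
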