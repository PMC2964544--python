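# Methods

## Scope and data model

`promid` implements the standard validation battery for three sum-scored MS
PRO instruments (PRIMUS QoL 0–22, PRIMUS Activities 0–30, U-FIS 0–66; all
higher-is-worse) and a responder-definition (RD) analysis anchored on the
EQ-5D utility. Item-level responses live in an `ItemResponseMatrix`
(subjects × items, NaN for missing) per instrument and timepoint (baseline,
month 12); clinical covariates (EDSS, relapses in the previous two years,
disease duration, EQ-5D utility at both timepoints, MSFC sub-scores) are
consumed as already-computed numbers. EQ-5D tariff computation, EDSS
clinical scoring and MSFC z-score construction are out of scope by design.

## Scoring

Totals are plain item sums. The default missing-item policy is
**complete-case**: any missing item leaves the scale total missing, which is
what produces differing per-scale n in the report tables. A **half-rule**
policy is available by configuration: if more than half of a scale's items
were answered, the total is the answered-item mean times the item count,
rounded half-up to an integer; otherwise missing. Change scores are
month 12 minus baseline and propagate missingness, so improvement on these
scales is negative; subjects observed at a single timepoint are excluded
from change analyses with a logged count.

Report rounding is **half-up** at 1 decimal (`promid.utils.round_half_up`):
clinical score tables round ties away from zero, where Python's default
banker's rounding would turn 2.15 into 2.1. Percentiles (median, IQR) use
linear interpolation between closest ranks. SDs are sample SDs (n − 1).

## Reliability and validity

- **Cronbach's alpha** = k/(k−1)·(1 − Σ item variances / total variance),
  sample variances, on listwise-complete rows; k and n are reported so the
  deletion choice is auditable. Requires ≥2 items, ≥3 complete cases and
  non-zero total variance.
- **Spearman correlations** use mid-ranks (ties averaged) and
  pairwise-complete deletion, with per-pair n. A constant column yields a
  missing correlation with a warning rather than a number.
- **Known-groups tests**: two groups → Mann-Whitney U, two-sided (exact p
  when both groups have n ≤ 8 and there are no ties, otherwise the normal
  approximation with tie and continuity corrections — scipy's `method="auto"`
  convention, which the test suite cross-checks against exhaustive
  permutation enumeration); three or more groups → Kruskal-Wallis H with tie
  correction. Groupings: EDSS bands 0–1.5 / 2–2.5 / 3–3.5 / 4–5.5 with
  inclusive printed edges (EDSS moves in 0.5 steps, so no observable value
  falls between bands; values above 5.5 go to a labelled out-of-protocol
  group excluded from the four-band test); relapse counts 1 / 2 / 3+ (zero
  counts, impossible under the emulated trial's activity criterion, go to a
  labelled excluded group); disease duration split at the sample median,
  with values exactly at the median assigned to the lower group
  (deterministic tie-break). No multiple-testing adjustment is applied.
  p-values below 0.01 print as "<0.01"; the CSV outputs keep full precision.

## Responder definitions

Anchor strata are defined on the raw (unrounded beyond the utility's
2-decimal grid) EQ-5D change: improvement = change in [0.074, 0.111]
(1–1.5 × the utility's published RD of 0.074), deterioration the mirrored
interval, stable = exactly zero. Band endpoints are inclusive; a small
epsilon (1e-9) guards against float representation noise only. Empty strata
are reported as *unavailable*, never as zero. The distribution-based
estimates use the baseline SD of **all baseline completers** (not the
change-score subsample) together with the baseline alpha:
SEM = s₁√(1−r), ES-equivalent change = ES·s₁ (0.30 and 0.50 by default;
0.50 is exactly the half-SD criterion — an identity the tests assert). The
final range takes absolute values of the five primary estimates — anchor
improvements are negative — after rounding each to 1 decimal, matching how
such tables are printed.

One documented inconsistency: applying SEM = s₁√(1−r) to the published
summary inputs for the PRIMUS scales (s₁ = 4.6, r = 0.88 for Activities;
s₁ = 4.3, r = 0.92 for QoL) gives 1.6 and 1.2 respectively, whereas the
published table prints 1.2 and 1.5 — the two cells appear transposed. The
package always computes from the formula; only the U-FIS SEM (2.4), which
is internally consistent, is treated as a reproduction target. The published
triangulated ranges are nevertheless reproduced exactly when the published
five-estimate sets are supplied to `rd_summary` as given.

## Synthetic cohort generator

The generator exists because the motivating trial's data are not public; it
emulates the *structure* the analyses assume, not the exact published
marginals.

- **Latent severity** θ ~ N(0, 1). Items follow a graded-response model:
  P(response ≥ k | θ) = logistic(a_j(θ − b_jk)) with strictly increasing
  thresholds per item; dichotomous items are the one-threshold case.
  Sampling is inverse-CDF with one uniform per item cell. Default item
  banks were calibrated once to the mild-severity profile of the target
  population: at n = 900 they give QoL floor ≈ 24%, Activities floor ≈ 40%,
  U-FIS floor ≈ 6%, alphas ≈ 0.90 / 0.87 / 0.96, and means/SDs near the
  published descriptives. The graded-response model was chosen over
  partial-credit as the simplest ordinal IRT model with ordered thresholds;
  any monotone ordinal model would serve.
- **EDSS** is banded from a noisy copy of the trait (weight 0.75) with
  thresholds placed so band shares are ≈ 44/29/15/12%, then a 0.5-step EDSS
  value is drawn uniformly within the band. Relapse counts are 1 + Poisson
  with band-dependent rates, capped at 4. Duration is lognormal
  (median ≈ 3.2 y) weakly linked to the trait. MSFC sub-scores are noisy
  monotone transforms of the trait with deliberately weak loadings (timed
  tests increase with severity, PASAT and the composite decrease).
- **Utility anchor**: u = clip(0.8 − 0.15·θ + ε, −0.2, 1.0) discretized to
  2 decimals so exact-zero "stable" strata occur. ε has a *persistent*
  per-subject component (sd 0.10, a response-style effect present at both
  timepoints) plus a small independent transient component (sd 0.02). The
  persistent component is what makes the observed utility change track the
  true latent change rather than noise.
- **Change model**: a mixture — 10% of subjects improve by a latent 0.6,
  10% deteriorate by 0.6, the rest stay put — so the default anchor change
  of an improver is 0.15·0.6 = 0.09, inside the 1–1.5 × RD band. The induced
  true scale change Δ* = E_θ[T(θ) − T(θ − shift)] is computed by 80-point
  Gauss–Hermite quadrature of the model-implied expected-total curve and
  stored in the cohort's ground truth; analysis modules never read ground
  truth.
- **Missingness**: independent Bernoulli per item cell (default 0.5%, so
  complete-case per-scale n stays near 90% of the cohort, mirroring the
  attrition pattern of real per-scale Ns) plus 5% month-12 dropout.
- Determinism: one `numpy` Generator seeded from `SimulationConfig.seed`;
  identical configs give bit-identical cohorts.

**Anchor-recovery experiments** use `recovery_config()`: anchor intercept
0.5 (mid-scale, so the 1.0 ceiling is never clipped — with the default 0.8
intercept, ceiling clipping would make band membership depend on severity
and bias the stratum mean relative to the unconditional Δ*), transient
anchor noise 0, and improve/deteriorate fractions of 0.25 with latent shift
0.8 mapped by a 0.125 loading to a utility change of 0.10. Under these
conditions the improve-stratum mean recovers −Δ* within 10% at n = 5000 in
effectively all seeded replicates (the acceptance suite requires ≥ 90% of
20).

### What passing tests do and do not show

The generator produces unidimensional scales with a single severity factor,
symmetric noise and missingness that is completely at random. Real PRO data
have multidimensional structure, differential item functioning across
languages, informative missingness and anchor changes contaminated by
recall effects. Passing the recovery and known-groups tests therefore shows
the *pipeline* is correct under its stated assumptions, not that the
published anchor-based point estimates (derived from ~15–17 real changers)
would be reproduced on real data.

## Problem sizes and numerical choices

Replicate-based checks use 20 seeded replicates at n = 900 (known-groups
structure) and n = 5000 (anchor recovery); single-cohort checks use n = 900,
the scale of the emulated trial sample. Gauss–Hermite quadrature uses 80
nodes (expected totals are smooth and bounded; 80 nodes is far past
convergence at these discriminations). Degenerate inputs fail loudly:
all-missing score vectors, zero total-score variance, a single non-empty
group, reliabilities outside [0, 1], negative EDSS/duration/relapse values.

## Known limitations

- Test–retest reproducibility is not implemented (no retest data exist in
  the emulated design); internal consistency is the only reliability
  estimate.
- The anchor analysis supports a single anchor (EQ-5D-style utility);
  global-rating-of-change anchors are not implemented.
- No bootstrap or confidence intervals on RD estimates; with realistic
  stratum sizes (tens of subjects) the anchor estimates are noisy, and the
  triangulated range should be read as preliminary guidance.
- The generator is calibrated qualitatively; it does not reproduce the
  published marginal tables exactly and is not a substitute for trial data.
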