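"""Sensitivity and PPV estimation with confidence intervals and suppression.

Sensitivity is TP/(TP+FN): among reference-standard transplants, the
proportion the algorithm identified.  PPV is TP/(TP+FP): among
algorithm-identified events, the proportion confirmed by the reference
standard.  Specificity and NPV are out of reach because the design defines
no true-negative pool.

Confidence intervals default to the Wilson score interval (well-behaved
near 0 and 1 at the small per-organ sample sizes here); exact
Clopper-Pearson is available as ``ci_method="exact"``.  The method used is
recorded in every estimate.

Small-cell suppression follows the privacy convention of health-data
custodians: any contributing cell count strictly between 0 and the
threshold (default 6) makes the estimate non-reportable; structural zeros
remain reportable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .algorithms import (
    AlgorithmSpec,
    ContingencyCounts,
    era_counts,
    identified_events,
)
from .linkage import dedup_source, match_events

__all__ = [
    "AccuracyEstimate",
    "sensitivity",
    "ppv",
    "suppress",
    "percent",
    "default_strata",
    "stratified_panel",
]

_CI_METHODS = {"wilson": "wilson", "exact": "beta"}


@dataclass(frozen=True)
class AccuracyEstimate:
    measure: str  # "sensitivity" | "ppv"
    estimate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int
    suppressed: bool
    algorithm: str
    organ: str = "all"
    era: str = "all"
    ci_method: str = "wilson"


def percent(p: float) -> int:
    """Proportion -> whole percent, rounding halves away from zero."""
    return int(math.floor(abs(p) * 100 + 0.5)) * (-1 if p < 0 else 1)


def _interval(count: int, nobs: int, ci_method: str) -> tuple[float, float]:
    if ci_method not in _CI_METHODS:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=_CI_METHODS[ci_method])
    return max(0.0, float(lo)), min(1.0, float(hi))


def sensitivity(counts: ContingencyCounts, ci_method: str = "wilson") -> AccuracyEstimate:
    """TP/(TP+FN) with a 95% CI; errors on an empty denominator."""
    n = counts.tp + counts.fn
    if n == 0:
        raise ValueError("sensitivity undefined: tp + fn == 0")
    lo, hi = _interval(counts.tp, n, ci_method)
    return AccuracyEstimate(
        measure="sensitivity",
        estimate=counts.tp / n,
        ci_low=lo,
        ci_high=hi,
        numerator=counts.tp,
        denominator=n,
        suppressed=False,
        algorithm=counts.algorithm,
        organ=counts.organ,
        era=counts.era,
        ci_method=ci_method,
    )


def ppv(counts: ContingencyCounts, ci_method: str = "wilson") -> AccuracyEstimate:
    """TP/(TP+FP) with a 95% CI; errors on an empty denominator."""
    n = counts.tp + counts.fp
    if n == 0:
        raise ValueError("ppv undefined: tp + fp == 0")
    lo, hi = _interval(counts.tp, n, ci_method)
    return AccuracyEstimate(
        measure="ppv",
        estimate=counts.tp / n,
        ci_low=lo,
        ci_high=hi,
        numerator=counts.tp,
        denominator=n,
        suppressed=False,
        algorithm=counts.algorithm,
        organ=counts.organ,
        era=counts.era,
        ci_method=ci_method,
    )


def suppress(estimate: AccuracyEstimate, threshold: int = 6) -> AccuracyEstimate:
    """Flag the estimate when a contributing cell is a small positive count.

    The contributing cells are the numerator and (denominator - numerator):
    TP and FN for sensitivity, TP and FP for PPV.  A cell equal to 0 is a
    structural zero and reportable; a cell in (0, threshold) is suppressed.
    """
    cells = (estimate.numerator, estimate.denominator - estimate.numerator)
    flagged = any(0 < c < threshold for c in cells)
    return replace(estimate, suppressed=flagged)


def default_strata(organs: Iterable[str]) -> list[tuple[str, str]]:
    """The reporting grid: overall and per-organ panels, plus era splits for
    the full cohort and for the largest subgroup (kidney)."""
    strata = [("all", "all")] + [(o, "all") for o in organs]
    strata += [("all", "pre"), ("all", "post")]
    if "kidney" in set(organs):
        strata += [("kidney", "pre"), ("kidney", "post")]
    return strata


def stratified_panel(
    eligible: pd.DataFrame,
    source_events: pd.DataFrame,
    algorithm_registry: Sequence[AlgorithmSpec],
    strata: Sequence[tuple[str, str]] | None = None,
    window_days: int = 7,
    era_boundary=None,
    ci_method: str = "wilson",
    suppress_threshold: int = 6,
    and_mode: str = "date-window",
) -> pd.DataFrame:
    """Full {algorithm x measure x stratum} accuracy grid.

    Returns a DataFrame with columns ``algorithm, measure, stratum_organ,
    stratum_era, estimate, ci_low, ci_high, numerator, denominator,
    suppressed, ci_method``.  Estimates whose denominator is zero (nothing
    to estimate in the stratum) are emitted with null numeric fields.
    """
    if len(algorithm_registry) == 0:
        raise ValueError("algorithm registry is empty")
    if strata is None:
        organs = sorted(eligible["organ"].unique())
        strata = default_strata(organs)
    if any(era != "all" for _, era in strata) and era_boundary is None:
        raise ValueError("era strata requested but era_boundary is None")

    deduped = dedup_source(source_events, window_days)
    # group strata by organ so each (algorithm, organ) match runs once
    eras_by_organ: dict[str, list[str]] = {}
    for organ, era in strata:
        eras_by_organ.setdefault(organ, []).append(era)

    rows = []
    for spec in algorithm_registry:
        ident_all = identified_events(
            spec, deduped, window_days, and_mode=and_mode, deduped=True
        )
        for organ, eras in eras_by_organ.items():
            refs = eligible if organ == "all" else eligible[eligible["organ"] == organ]
            ident = ident_all if organ == "all" else ident_all[ident_all["organ"] == organ]
            result = match_events(refs, ident, window_days)
            for era in eras:
                tp, fn, fp = era_counts(result, era, era_boundary)
                counts = ContingencyCounts(
                    tp=tp, fn=fn, fp=fp, algorithm=spec.label, organ=organ, era=era
                )
                for estimator in (sensitivity, ppv):
                    try:
                        est = suppress(estimator(counts, ci_method), suppress_threshold)
                        rows.append(
                            dict(
                                algorithm=est.algorithm,
                                measure=est.measure,
                                stratum_organ=organ,
                                stratum_era=era,
                                estimate=est.estimate,
                                ci_low=est.ci_low,
                                ci_high=est.ci_high,
                                numerator=est.numerator,
                                denominator=est.denominator,
                                suppressed=est.suppressed,
                                ci_method=ci_method,
                            )
                        )
                    except ValueError:
                        rows.append(
                            dict(
                                algorithm=spec.label,
                                measure="sensitivity" if estimator is sensitivity else "ppv",
                                stratum_organ=organ,
                                stratum_era=era,
                                estimate=float("nan"),
                                ci_low=float("nan"),
                                ci_high=float("nan"),
                                numerator=0,
                                denominator=0,
                                suppressed=False,
                                ci_method=ci_method,
                            )
                        )
    return pd.DataFrame(rows)
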