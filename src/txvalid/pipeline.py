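"""End-to-end validation run: clean, link, evaluate, summarize, report."""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import pandas as pd

from .accuracy import stratified_panel
from .algorithms import AlgorithmSpec, default_registry
from .cohort import clean_reference
from .linkage import dedup_source, match_events
from .reporting import DateConcordanceSummary, ReportBundle, build_report, date_concordance

__all__ = ["ValidationRun", "run_validation"]


@dataclass
class ValidationRun:
    eligible: pd.DataFrame
    ledger: pd.DataFrame
    panel: pd.DataFrame
    concordance: list[DateConcordanceSummary]
    report: ReportBundle


def run_validation(
    reference: pd.DataFrame,
    sources: pd.DataFrame,
    study_window: tuple[date, date],
    center_name: str = "SickKids",
    registry: Sequence[AlgorithmSpec] | None = None,
    window_days: int = 7,
    era_boundary: date | None = date(2002, 4, 1),
    ci_method: str = "wilson",
    suppress_threshold: int = 6,
    and_mode: str = "date-window",
    config: Mapping | None = None,
    seed: int | None = None,
) -> ValidationRun:
    """Run the full validation pipeline on reference and source tables.

    Steps: exclusion cascade on the reference events; within-source
    deduplication; per-source date concordance of matched pairs; the
    algorithm x measure x stratum accuracy panel; and the assembled,
    suppression-aware report.
    """
    registry = list(registry) if registry is not None else default_registry()
    eligible, ledger = clean_reference(reference, study_window, center_name)
    deduped = dedup_source(sources, window_days)

    concordance = []
    for source in sorted(deduped["source"].unique()):
        sub = deduped[deduped["source"] == source]
        result = match_events(eligible, sub, window_days)
        concordance.append(date_concordance(result, label=source))

    panel = stratified_panel(
        eligible,
        deduped,
        registry,
        window_days=window_days,
        era_boundary=era_boundary,
        ci_method=ci_method,
        suppress_threshold=suppress_threshold,
        and_mode=and_mode,
    )
    report = build_report(panel, concordance, ledger, config=config, seed=seed)
    return ValidationRun(eligible, ledger, panel, concordance, report)
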