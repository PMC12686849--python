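"""Date-concordance summaries and final report assembly.

Date concordance describes how far administrative transplant dates sit from
the reference-center date among matched pairs.  The signed convention is
source minus reference (positive = administrative date later).  Quantiles
of the absolute differences use linear interpolation between closest ranks
(numpy's default), a choice that must be fixed for the 25th/75th
percentiles to be reproducible.

The report bundle mirrors the shape of a validation-study results section:
per-stratum tables ranking algorithms by sensitivity then PPV, date
concordance per source, the exclusion ledger, and a config hash + seed so
two runs of the same study are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .linkage import MatchResult

__all__ = ["DateConcordanceSummary", "date_concordance", "ReportBundle", "build_report"]


@dataclass(frozen=True)
class DateConcordanceSummary:
    """Central-tendency summary of date differences for one source/algorithm.

    All statistics are in days.  ``mean_signed``/``sd_signed`` summarize the
    signed differences; the remaining fields summarize their absolute
    values.  With zero pairs every statistic is NaN.
    """

    label: str
    n_pairs: int
    mean_signed: float
    sd_signed: float
    mean_abs: float
    sd_abs: float
    median_abs: float
    q25: float
    q75: float


def date_concordance(matches: MatchResult, label: str = "") -> DateConcordanceSummary:
    """Summarize signed and absolute date differences of the matched pairs."""
    n = matches.tp
    if n == 0:
        nan = float("nan")
        return DateConcordanceSummary(label, 0, nan, nan, nan, nan, nan, nan, nan)
    diffs = matches.pairs["diff_days"].to_numpy(dtype=float)
    ab = np.abs(diffs)
    sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    q25, med, q75 = (float(q) for q in np.percentile(ab, [25, 50, 75]))
    return DateConcordanceSummary(
        label=label,
        n_pairs=n,
        mean_signed=float(np.mean(diffs)),
        sd_signed=sd(diffs),
        mean_abs=float(np.mean(ab)),
        sd_abs=sd(ab),
        median_abs=med,
        q25=q25,
        q75=q75,
    )


def concordance_table(summaries: Sequence[DateConcordanceSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                label=s.label,
                n_pairs=s.n_pairs,
                mean_signed=s.mean_signed,
                sd_signed=s.sd_signed,
                mean_abs=s.mean_abs,
                sd_abs=s.sd_abs,
                median_abs=s.median_abs,
                q25=s.q25,
                q75=s.q75,
            )
            for s in summaries
        ]
    )


SUPPRESSED_MARK = "<6"


@dataclass
class ReportBundle:
    """Assembled validation report.

    ``tables`` maps (organ, era) strata to ranked algorithm tables with
    rendered percent estimates ("91% (89-93)") and suppressed cells shown
    as ``"<6"``.  ``removed_algorithms`` lists single-source algorithms
    whose overall sensitivity cell was suppressed — these are dropped from
    the ranked tables, the way a diagnostic-code source with under-threshold
    alignment is removed from analysis.
    """

    tables: dict[tuple[str, str], pd.DataFrame]
    concordance: pd.DataFrame
    ledger: pd.DataFrame | None
    best_single_source: str | None
    removed_algorithms: list[str]
    config_hash: str
    seed: int | None

    def render(self) -> str:
        lines = []
        lines.append("Transplant ascertainment validation report")
        lines.append(f"config sha256: {self.config_hash}  seed: {self.seed}")
        lines.append("")
        if self.ledger is not None and len(self.ledger):
            lines.append("Exclusion cascade")
            lines.append(self.ledger.to_string(index=False))
            lines.append("")
        for (organ, era), table in self.tables.items():
            lines.append(f"Stratum: organ={organ}, era={era}")
            lines.append(table.to_string(index=False))
            lines.append("")
        if self.removed_algorithms:
            lines.append(
                "Removed from analysis (cell size under the suppression "
                f"threshold): {', '.join(self.removed_algorithms)}"
            )
            lines.append("")
        if self.best_single_source:
            lines.append(f"Best single-source algorithm: {self.best_single_source}")
            lines.append("")
        if len(self.concordance):
            lines.append("Date concordance (days, matched pairs)")
            lines.append(self.concordance.to_string(index=False))
            lines.append("")
        return "\n".join(lines)


def _fmt_cell(row: pd.Series) -> str:
    if row["suppressed"]:
        return SUPPRESSED_MARK
    if row["denominator"] == 0 or not np.isfinite(row["estimate"]):
        return "n/a"
    from .accuracy import percent

    return f"{percent(row['estimate'])}% ({percent(row['ci_low'])}-{percent(row['ci_high'])})"


def build_report(
    accuracy_panel: pd.DataFrame,
    concordance_summaries: Sequence[DateConcordanceSummary] = (),
    ledger: pd.DataFrame | None = None,
    config: Mapping | None = None,
    seed: int | None = None,
) -> ReportBundle:
    """Assemble the ranked, suppression-aware report from the accuracy panel.

    Algorithms are ranked within each stratum by sensitivity, ties broken by
    PPV; suppressed cells render as ``"<6"``.  Single-source algorithms whose
    overall (all-organ, all-era) sensitivity is suppressed are removed from
    every ranked table and listed separately.
    """
    if len(accuracy_panel) == 0:
        raise ValueError("accuracy panel is empty (no algorithms evaluated)")
    panel = accuracy_panel.copy()

    overall = panel[
        (panel["stratum_organ"] == "all")
        & (panel["stratum_era"] == "all")
        & (panel["measure"] == "sensitivity")
    ]
    # an algorithm with a suppressed overall sensitivity and no OR/AND
    # structure carries no reportable signal: drop it, as a custodian would
    removed = sorted(
        lbl
        for lbl in overall.loc[overall["suppressed"], "algorithm"].unique()
        if " or " not in lbl and " and " not in lbl
    )

    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for (organ, era), grp in panel.groupby(["stratum_organ", "stratum_era"], sort=True):
        grp = grp[~grp["algorithm"].isin(removed)]
        wide_rows = []
        for lbl, sub in grp.groupby("algorithm", sort=True):
            sens = sub[sub["measure"] == "sensitivity"]
            pv = sub[sub["measure"] == "ppv"]
            s_row = sens.iloc[0] if len(sens) else None
            p_row = pv.iloc[0] if len(pv) else None
            sort_s = (
                s_row["estimate"]
                if s_row is not None and not s_row["suppressed"] and s_row["denominator"] > 0
                else -1.0
            )
            sort_p = (
                p_row["estimate"]
                if p_row is not None and not p_row["suppressed"] and p_row["denominator"] > 0
                else -1.0
            )
            wide_rows.append(
                dict(
                    algorithm=lbl,
                    sensitivity=_fmt_cell(s_row) if s_row is not None else "n/a",
                    ppv=_fmt_cell(p_row) if p_row is not None else "n/a",
                    _sort_s=sort_s,
                    _sort_p=sort_p,
                )
            )
        wide = pd.DataFrame(wide_rows).sort_values(
            ["_sort_s", "_sort_p", "algorithm"], ascending=[False, False, True]
        )
        tables[(organ, era)] = wide.drop(columns=["_sort_s", "_sort_p"]).reset_index(drop=True)

    singles = overall[
        (~overall["suppressed"])
        & (overall["denominator"] > 0)
        & overall["algorithm"].map(lambda s: " or " not in s and " and " not in s)
    ]
    best_single = None
    if len(singles):
        pv = panel[
            (panel["stratum_organ"] == "all")
            & (panel["stratum_era"] == "all")
            & (panel["measure"] == "ppv")
        ].set_index("algorithm")["estimate"]
        ranked = singles.assign(_ppv=singles["algorithm"].map(pv)).sort_values(
            ["estimate", "_ppv", "algorithm"], ascending=[False, False, True]
        )
        best_single = str(ranked["algorithm"].iloc[0])

    cfg = dict(config) if config is not None else {}
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    return ReportBundle(
        tables=tables,
        concordance=concordance_table(list(concordance_summaries)),
        ledger=ledger,
        best_single_source=best_single,
        removed_algorithms=removed,
        config_hash=config_hash,
        seed=seed,
    )
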