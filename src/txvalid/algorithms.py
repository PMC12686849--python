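"""Case-ascertainment algorithms as Boolean expressions over sources.

An algorithm declares a patient-event "identified" from single sources or
AND/OR combinations of them.  Record-level semantics:

OR   — union of the leaves' deduplicated events; within a patient, events
       from different sources are merged into one identified event when they
       fall within the date window of each other (greedy clustering anchored
       at the earliest date; the merged event takes the earliest date).
AND  — an event is identified only when every leaf contributes an event for
       the patient with all pairwise date differences inside the window
       (the default "date-window" mode).  The looser "patient-level" mode
       requires only that the patient appear in every leaf source,
       regardless of dates.

The default registry holds the ten algorithms evaluated against the
reference standard: three single sources, six pairwise OR/AND combinations,
and the triple OR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import pandas as pd

from .config import SOURCES
from .linkage import _optimal_pairing, dedup_source, match_events

__all__ = [
    "Leaf",
    "Or",
    "And",
    "AlgorithmSpec",
    "ContingencyCounts",
    "parse_expression",
    "default_registry",
    "identified_events",
    "evaluate_algorithm",
]


@dataclass(frozen=True)
class Leaf:
    source: str

    def sources(self) -> set[str]:
        return {self.source}


@dataclass(frozen=True)
class Or:
    children: tuple

    def sources(self) -> set[str]:
        return set().union(*(c.sources() for c in self.children))


@dataclass(frozen=True)
class And:
    children: tuple

    def sources(self) -> set[str]:
        return set().union(*(c.sources() for c in self.children))


Expr = Union[Leaf, Or, And]


@dataclass(frozen=True)
class AlgorithmSpec:
    """A labeled ascertainment rule over administrative sources."""

    label: str
    expression: Expr

    def sources(self) -> set[str]:
        return self.expression.sources()

    @property
    def is_single_source(self) -> bool:
        return isinstance(self.expression, Leaf)

    @classmethod
    def from_string(cls, text: str) -> "AlgorithmSpec":
        return cls(label=text, expression=parse_expression(text))


def parse_expression(text: str, known_sources: Sequence[str] = SOURCES) -> Expr:
    """Parse expressions like ``"CIHI-DAD-p or CORR or OHIP"``.

    Only homogeneous expressions (all-OR or all-AND) are supported, which
    covers every algorithm in the registry; mixing connectives requires
    building the tree directly.
    """
    has_or = " or " in text
    has_and = " and " in text
    if has_or and has_and:
        raise ValueError(f"mixed and/or in {text!r}; build the expression tree directly")
    parts = [p.strip() for p in text.split(" or " if has_or else " and ")]
    for p in parts:
        if p not in known_sources:
            raise ValueError(f"unknown source {p!r} in algorithm {text!r}")
    leaves = tuple(Leaf(p) for p in parts)
    if len(leaves) == 1:
        return leaves[0]
    return Or(leaves) if has_or else And(leaves)


def default_registry() -> list[AlgorithmSpec]:
    """The ten algorithms of the primary analysis."""
    labels = [
        "CORR",
        "CIHI-DAD-p",
        "OHIP",
        "CIHI-DAD-p or CORR",
        "CORR or OHIP",
        "CIHI-DAD-p or OHIP",
        "CIHI-DAD-p and CORR",
        "CIHI-DAD-p and OHIP",
        "CORR and OHIP",
        "CIHI-DAD-p or CORR or OHIP",
    ]
    return [AlgorithmSpec.from_string(lbl) for lbl in labels]


@dataclass(frozen=True)
class ContingencyCounts:
    """TP/FN/FP for one algorithm in one stratum.

    TN is undefined by design: the study frame has no enumerable pool of
    true negatives, so specificity/NPV are not computable.
    """

    tp: int
    fn: int
    fp: int
    algorithm: str
    organ: str = "all"
    era: str = "all"


_EVENT_COLUMNS = ["patient_key", "event_date", "organ", "sources"]


def _merge_cluster(events: pd.DataFrame, window_days: int) -> pd.DataFrame:
    """Greedy earliest-anchor clustering across sources within a patient."""
    if len(events) == 0:
        return events
    df = events.sort_values(["patient_key", "event_date", "organ"], kind="mergesort")
    rows = []
    for _key, grp in df.groupby("patient_key", sort=True):
        anchor = None
        for _, row in grp.iterrows():
            if anchor is None or (row["event_date"] - anchor["event_date"]).days > window_days:
                if anchor is not None:
                    rows.append(anchor)
                anchor = row.to_dict()
            else:
                anchor["sources"] = anchor["sources"] | row["sources"]
        rows.append(anchor)
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS).reset_index(drop=True)


def _and_merge(a: pd.DataFrame, b: pd.DataFrame, window_days: int) -> pd.DataFrame:
    """Pair events of two operands per patient; keep only paired events.

    Pairing reuses the exact per-patient assignment of the linkage stage;
    a merged identification takes the earlier constituent's date and organ.
    """
    rows = []
    a_groups = {k: g for k, g in a.groupby("patient_key", sort=True)}
    b_groups = {k: g for k, g in b.groupby("patient_key", sort=True)}
    for key in sorted(set(a_groups) & set(b_groups), key=str):
        ga = a_groups[key].sort_values("event_date", kind="mergesort")
        gb = b_groups[key].sort_values("event_date", kind="mergesort")
        epoch = ga["event_date"].iloc[0]
        da = [(d - epoch).days for d in ga["event_date"]]
        db = [(d - epoch).days for d in gb["event_date"]]
        for i, j in _optimal_pairing(da, db, window_days):
            ra, rb = ga.iloc[i], gb.iloc[j]
            first = ra if ra["event_date"] <= rb["event_date"] else rb
            rows.append(
                dict(
                    patient_key=key,
                    event_date=first["event_date"],
                    organ=first["organ"],
                    sources=ra["sources"] | rb["sources"],
                )
            )
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def identified_events(
    spec: AlgorithmSpec,
    source_events: pd.DataFrame,
    window_days: int = 7,
    and_mode: str = "date-window",
    deduped: bool = False,
) -> pd.DataFrame:
    """Events the algorithm identifies.

    Parameters
    ----------
    source_events : DataFrame
        Raw or deduplicated records (``source, patient_key, event_date,
        organ``); set ``deduped=True`` to skip within-source deduplication.
    and_mode : {"date-window", "patient-level"}
        AND semantics (see module docstring).

    Returns
    -------
    DataFrame with columns ``patient_key, event_date, organ, sources``
    (``sources`` is the frozenset of contributing source labels).
    """
    if and_mode not in ("date-window", "patient-level"):
        raise ValueError(f"unknown and_mode {and_mode!r}")
    present = set(source_events["source"].unique()) if len(source_events) else set()
    known = set(SOURCES) | present
    unknown = spec.sources() - known
    if unknown:
        raise ValueError(f"algorithm {spec.label!r} references unknown sources {sorted(unknown)}")
    events = source_events if deduped else dedup_source(source_events, window_days)

    def eval_expr(expr: Expr) -> pd.DataFrame:
        if isinstance(expr, Leaf):
            sub = events[events["source"] == expr.source]
            out = sub[["patient_key", "event_date", "organ"]].copy()
            out["sources"] = [frozenset({expr.source}) for _ in range(len(sub))]
            return out.reset_index(drop=True)
        children = [eval_expr(c) for c in expr.children]
        if isinstance(expr, Or):
            merged = pd.concat(children, ignore_index=True)
            if len(merged) == 0:
                return pd.DataFrame(columns=_EVENT_COLUMNS)
            return _merge_cluster(merged, window_days)
        # And
        if and_mode == "patient-level":
            keys = set(children[0]["patient_key"])
            for c in children[1:]:
                keys &= set(c["patient_key"])
            merged = pd.concat(children, ignore_index=True)
            merged = merged[merged["patient_key"].isin(keys)]
            if len(merged) == 0:
                return pd.DataFrame(columns=_EVENT_COLUMNS)
            # one identified event per patient at the earliest date seen
            merged = merged.sort_values(["patient_key", "event_date", "organ"], kind="mergesort")
            agg = merged.groupby("patient_key", sort=True).agg(
                event_date=("event_date", "first"),
                organ=("organ", "first"),
                sources=("sources", lambda s: frozenset().union(*s)),
            )
            return agg.reset_index()[_EVENT_COLUMNS]
        out = children[0]
        for c in children[1:]:
            out = _and_merge(out, c, window_days)
        return out.reset_index(drop=True)

    result = eval_expr(spec.expression)
    return result.sort_values(
        ["patient_key", "event_date"], kind="mergesort"
    ).reset_index(drop=True)


def evaluate_algorithm(
    spec: AlgorithmSpec,
    eligible: pd.DataFrame,
    source_events: pd.DataFrame,
    window_days: int = 7,
    organ: str = "all",
    era: str = "all",
    era_boundary=None,
    and_mode: str = "date-window",
    deduped: bool = False,
) -> ContingencyCounts:
    """Contingency counts for one algorithm in one stratum.

    Identified events are matched to eligible reference events with the
    standard linkage semantics.  Organ strata filter the reference side by
    recorded organ and the identified side by its (source-derived) organ
    label *before* matching; era strata are assigned *after* matching — TP
    and FN by the reference transplant date, FP by the identified event's
    own date — so a match never straddles stratum boundaries artificially.
    """
    ident = identified_events(spec, source_events, window_days, and_mode, deduped)
    refs = eligible
    if organ != "all":
        refs = refs[refs["organ"] == organ]
        ident = ident[ident["organ"] == organ]
    result = match_events(refs, ident, window_days)
    tp, fn, fp = era_counts(result, era, era_boundary)
    return ContingencyCounts(tp=tp, fn=fn, fp=fp, algorithm=spec.label, organ=organ, era=era)


def era_counts(result, era: str, era_boundary=None) -> tuple[int, int, int]:
    """(tp, fn, fp) of a match result restricted to one coding era.

    TP and FN are assigned by the reference transplant date, FP by the
    identified event's own date; ``era="all"`` returns the raw counts.
    """
    if era == "all":
        return result.tp, result.fn, result.fp
    if era_boundary is None:
        raise ValueError("era stratification requires era_boundary")
    boundary = pd.Timestamp(era_boundary)

    def in_era(dates: pd.Series) -> pd.Series:
        return (dates >= boundary) if era == "post" else (dates < boundary)

    tp = int(in_era(result.pairs["ref_date"]).sum()) if result.tp else 0
    fn = (
        int(in_era(result.unmatched_reference["transplant_date"]).sum())
        if result.fn
        else 0
    )
    fp = int(in_era(result.unmatched_source["event_date"]).sum()) if result.fp else 0
    return tp, fn, fp
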