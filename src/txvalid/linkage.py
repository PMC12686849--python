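"""Deterministic record linkage with a date window.

Administrative records are first collapsed into *source events* (duplicate
rows for the same admission cluster within a date window), then matched
one-to-one to eligible reference events.  A reference event and a source
event may pair only when their patient keys are equal and their dates lie
within ``window_days`` of each other (inclusive; the default 7-day window
reads "within 7 days" inclusively).

Within each patient the pairing is solved exactly (candidate sets are
small): maximize the number of in-window pairs, then minimize the total
absolute date difference, then break remaining ties by pairing earlier
reference events with earlier source events.  One-to-one matching is
deliberate — letting one administrative record stand for two transplants
would inflate true-positive counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import ORGANS

__all__ = ["MatchResult", "dedup_source", "match_events", "match_by_organ"]


@dataclass
class MatchResult:
    """One-to-one linkage outcome.

    ``pairs`` holds one row per matched (reference, source) pair with the
    signed date difference ``diff_days`` (source minus reference; positive
    means the administrative date is later).  ``unmatched_reference`` rows
    are false negatives; ``unmatched_source`` rows are false positives.
    """

    pairs: pd.DataFrame
    unmatched_reference: pd.DataFrame
    unmatched_source: pd.DataFrame

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return len(self.unmatched_reference)

    @property
    def fp(self) -> int:
        return len(self.unmatched_source)


_PAIR_COLUMNS = [
    "patient_key", "ref_date", "src_date", "diff_days", "ref_organ", "src_organ",
]


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=_PAIR_COLUMNS)


def dedup_source(records: pd.DataFrame, window_days: int = 7) -> pd.DataFrame:
    """Collapse duplicate rows into source events.

    Within each (source, patient_key), records are clustered greedily in
    date order: a record joins the open cluster if it falls within
    ``window_days`` of the cluster's *earliest* date, otherwise it starts a
    new cluster.  Each cluster is represented by its earliest record (whose
    organ label the event inherits).
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    if len(records) == 0:
        return records.copy()
    df = records.sort_values(
        ["source", "patient_key", "event_date", "organ"], kind="mergesort"
    ).reset_index(drop=True)
    keep = []
    anchor_key = None
    anchor_date = None
    for i, row in df.iterrows():
        group = (row["source"], row["patient_key"])
        if group != anchor_key or (row["event_date"] - anchor_date).days > window_days:
            keep.append(i)
            anchor_key = group
            anchor_date = row["event_date"]
    return df.loc[keep].reset_index(drop=True)


def _optimal_pairing(ref_days: list[int], src_days: list[int], window: int):
    """Exact per-patient assignment.

    Returns a list of (ref_index, src_index) pairs that maximizes the pair
    count, then minimizes total |date difference|, then is lexicographically
    smallest in (ref, src) index order — i.e., earlier reference events pair
    with earlier source events on remaining ties.  Inputs must be sorted
    ascending.
    """
    n, m = len(ref_days), len(src_days)
    best: list[tuple] = [None]

    def rec(i: int, used: set, pairs: list, total: int) -> None:
        if i == n:
            key = (-len(pairs), total, tuple(pairs))
            if best[0] is None or key < best[0][0]:
                best[0] = (key, list(pairs))
            return
        for j in range(m):
            if j in used:
                continue
            d = abs(ref_days[i] - src_days[j])
            if d <= window:
                used.add(j)
                pairs.append((i, j))
                rec(i + 1, used, pairs, total + d)
                pairs.pop()
                used.remove(j)
        rec(i + 1, used, pairs, total)

    rec(0, set(), [], 0)
    return best[0][1]


def match_events(
    eligible: pd.DataFrame, source_events: pd.DataFrame, window_days: int = 7
) -> MatchResult:
    """Match source events one-to-one to reference events per patient key.

    Both inputs should already be deduplicated.  ``eligible`` needs columns
    ``patient_key, transplant_date`` (``organ`` optional); ``source_events``
    needs ``patient_key, event_date`` (``organ`` optional).
    """
    if window_days < 0:
        raise ValueError("window_days must be >= 0")
    refs = eligible.reset_index(drop=True)
    srcs = source_events.reset_index(drop=True)
    matched_ref: list[int] = []
    matched_src: list[int] = []
    pair_rows: list[dict] = []

    ref_groups = {k: list(v) for k, v in refs.groupby("patient_key").groups.items()}
    src_groups = {k: list(v) for k, v in srcs.groupby("patient_key").groups.items()}
    for key in sorted(set(ref_groups) & set(src_groups), key=str):
        ri = sorted(ref_groups[key], key=lambda i: refs["transplant_date"].iloc[i])
        si = sorted(src_groups[key], key=lambda i: srcs["event_date"].iloc[i])
        epoch = refs["transplant_date"].iloc[ri[0]]
        ref_days = [(refs["transplant_date"].iloc[i] - epoch).days for i in ri]
        src_days = [(srcs["event_date"].iloc[i] - epoch).days for i in si]
        for a, b in _optimal_pairing(ref_days, src_days, window_days):
            i, j = ri[a], si[b]
            matched_ref.append(i)
            matched_src.append(j)
            pair_rows.append(
                dict(
                    patient_key=key,
                    ref_date=refs["transplant_date"].iloc[i],
                    src_date=srcs["event_date"].iloc[j],
                    diff_days=(srcs["event_date"].iloc[j] - refs["transplant_date"].iloc[i]).days,
                    ref_organ=refs["organ"].iloc[i] if "organ" in refs else None,
                    src_organ=srcs["organ"].iloc[j] if "organ" in srcs else None,
                )
            )

    pairs = pd.DataFrame(pair_rows, columns=_PAIR_COLUMNS) if pair_rows else _empty_pairs()
    unmatched_reference = refs.drop(index=matched_ref).reset_index(drop=True)
    unmatched_source = srcs.drop(index=matched_src).reset_index(drop=True)
    return MatchResult(pairs, unmatched_reference, unmatched_source)


def match_by_organ(
    eligible: pd.DataFrame,
    source_events: pd.DataFrame,
    window_days: int = 7,
    organ: str = "kidney",
    require_source_organ: bool = True,
) -> MatchResult:
    """Per-organ matching: filter both sides to ``organ``, then match.

    By default source events are filtered by their own organ label (an
    event mislabeled in the source is analyzed only in its labeled organ
    stratum).  With ``require_source_organ=False`` only the reference side
    is filtered and source events of any organ may match.
    """
    if organ not in ORGANS:
        raise ValueError(f"unknown organ {organ!r}")
    refs = eligible[eligible["organ"] == organ]
    srcs = (
        source_events[source_events["organ"] == organ]
        if require_source_organ
        else source_events
    )
    return match_events(refs, srcs, window_days)
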