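"""Linkage semantics: dedup clustering and optimal per-patient matching."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txvalid import (
    SimulationConfig,
    dedup_source,
    match_by_organ,
    match_events,
    simulate_study,
)


# --- independent oracle ----------------------------------------------------

def oracle_best_pairing(ref_days, src_days, window):
    """Enumerate every injective pairing; return the optimum.

    Independent of the implementation: iterates over all subsets of
    reference indices and all orderings of source indices.
    """
    n, m = len(ref_days), len(src_days)
    best_key, best = None, []
    for k in range(min(n, m), -1, -1):
        for ref_sub in itertools.combinations(range(n), k):
            for src_perm in itertools.permutations(range(m), k):
                if any(
                    abs(ref_days[i] - src_days[j]) > window
                    for i, j in zip(ref_sub, src_perm)
                ):
                    continue
                pairs = sorted(zip(ref_sub, src_perm))
                total = sum(abs(ref_days[i] - src_days[j]) for i, j in pairs)
                key = (-k, total, tuple(pairs))
                if best_key is None or key < best_key:
                    best_key, best = key, pairs
        if best_key is not None:
            break  # no larger pairing can exist
    return best


def frame_from_days(ref_days, src_days):
    epoch = pd.Timestamp("2000-01-01")
    refs = pd.DataFrame(
        {
            "patient_key": "P1",
            "transplant_date": [epoch + pd.Timedelta(days=int(d)) for d in ref_days],
            "organ": "kidney",
        }
    )
    srcs = pd.DataFrame(
        {
            "source": "CORR",
            "patient_key": "P1",
            "event_date": [epoch + pd.Timedelta(days=int(d)) for d in src_days],
            "organ": "kidney",
        }
    )
    return refs, srcs


# --- dedup -----------------------------------------------------------------

def test_dedup_collapses_rows_within_window(src_frame):
    records = src_frame(
        [dict(event_date="2005-03-10"), dict(event_date="2005-03-13")]
    )
    out = dedup_source(records, 7)
    assert len(out) == 1
    assert out["event_date"].iloc[0] == pd.Timestamp("2005-03-10")


def test_dedup_keeps_events_beyond_window(src_frame):
    records = src_frame(
        [dict(event_date="2005-03-10"), dict(event_date="2005-04-09")]
    )
    assert len(dedup_source(records, 7)) == 2


def test_dedup_empty_input():
    empty = pd.DataFrame(columns=["record_id", "source", "patient_key", "event_date", "organ"])
    assert len(dedup_source(empty, 7)) == 0


def test_dedup_anchors_at_cluster_earliest_date(src_frame):
    # chain 0, 5, 10: the third row is 10 days from the anchor, so it opens
    # a new cluster even though it is within 7 days of the second row
    records = src_frame(
        [
            dict(event_date="2005-03-01"),
            dict(event_date="2005-03-06"),
            dict(event_date="2005-03-11"),
        ]
    )
    out = dedup_source(records, 7)
    assert list(out["event_date"].dt.day) == [1, 11]


# --- matching --------------------------------------------------------------

def test_single_candidate_within_window_matches(ref_frame, src_frame):
    refs = ref_frame([dict(transplant_date="2005-03-10")])
    srcs = src_frame([dict(event_date="2005-03-12")])
    result = match_events(refs, srcs, 7)
    assert result.tp == 1 and result.fn == 0 and result.fp == 0
    assert result.pairs["diff_days"].iloc[0] == 2


def test_closer_candidate_wins_other_becomes_fp(ref_frame, src_frame):
    refs = ref_frame([dict(transplant_date="2005-03-10")])
    srcs = src_frame(
        [dict(event_date="2005-03-09"), dict(event_date="2005-03-16")]
    )
    result = match_events(refs, srcs, 7)
    assert result.tp == 1 and result.fp == 1
    assert result.pairs["diff_days"].iloc[0] == -1


def test_equidistant_source_pairs_with_earlier_reference(ref_frame, src_frame):
    refs = ref_frame(
        [
            dict(transplant_date="2005-03-02"),
            dict(transplant_date="2005-03-10"),
        ]
    )
    srcs = src_frame([dict(event_date="2005-03-06")])
    result = match_events(refs, srcs, 7)
    assert result.tp == 1
    assert result.pairs["ref_date"].iloc[0] == pd.Timestamp("2005-03-02")


def test_counts_are_conserved(ref_frame, src_frame):
    refs = ref_frame(
        [dict(patient_key=f"P{i}", transplant_date=f"2005-03-{10 + i:02d}") for i in range(5)]
    )
    srcs = src_frame(
        [dict(patient_key="P0", event_date="2005-03-11"), dict(patient_key="P9", event_date="2005-03-11")]
    )
    result = match_events(refs, srcs, 7)
    assert result.tp + result.fn == len(refs)
    assert result.tp + result.fp == len(srcs)


def test_window_zero_equals_exact_date_join():
    rng = np.random.default_rng(2024)
    for _ in range(50):
        n_pat = rng.integers(1, 6)
        rows_r, rows_s = [], []
        for p in range(n_pat):
            # distinct dates per patient per side keep the join one-to-one
            ref_d = rng.choice(60, size=rng.integers(0, 4), replace=False)
            src_d = rng.choice(60, size=rng.integers(0, 4), replace=False)
            rows_r += [(f"P{p}", d) for d in ref_d]
            rows_s += [(f"P{p}", d) for d in src_d]
        if not rows_r or not rows_s:
            continue
        epoch = pd.Timestamp("2000-01-01")
        refs = pd.DataFrame(rows_r, columns=["patient_key", "d"])
        refs["transplant_date"] = epoch + pd.to_timedelta(refs.pop("d"), unit="D")
        refs["organ"] = "kidney"
        srcs = pd.DataFrame(rows_s, columns=["patient_key", "d"])
        srcs["event_date"] = epoch + pd.to_timedelta(srcs.pop("d"), unit="D")
        srcs["organ"] = "kidney"
        result = match_events(refs, srcs, 0)
        join = refs.merge(
            srcs, left_on=["patient_key", "transplant_date"], right_on=["patient_key", "event_date"]
        )
        assert result.tp == len(join)
        assert (result.pairs["diff_days"] == 0).all() if result.tp else True


@pytest.mark.parametrize("window", [0, 3, 7])
def test_matcher_agrees_with_exhaustive_enumeration(window):
    rng = np.random.default_rng(99 + window)
    for _ in range(300):
        n = int(rng.integers(0, 4))
        m = int(rng.integers(0, 5))
        ref_days = sorted(int(x) for x in rng.integers(0, 25, size=n))
        src_days = sorted(int(x) for x in rng.integers(0, 25, size=m))
        refs, srcs = frame_from_days(ref_days, src_days)
        result = match_events(refs, srcs, window)
        expected = oracle_best_pairing(ref_days, src_days, window)
        got = sorted(
            zip(
                [(d - pd.Timestamp("2000-01-01")).days for d in result.pairs["ref_date"]],
                [(d - pd.Timestamp("2000-01-01")).days for d in result.pairs["src_date"]],
            )
        )
        want = sorted((ref_days[i], src_days[j]) for i, j in expected)
        assert got == want, (ref_days, src_days, window)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    ref_days=st.lists(st.integers(0, 40), max_size=4),
    src_days=st.lists(st.integers(0, 40), max_size=5),
    window=st.integers(0, 10),
)
def test_matching_invariants_hold_on_arbitrary_inputs(ref_days, src_days, window):
    """Counts are conserved, pairs respect the window, and each event is
    used at most once."""
    refs, srcs = frame_from_days(sorted(ref_days), sorted(src_days))
    result = match_events(refs, srcs, window)
    assert result.tp + result.fn == len(refs)
    assert result.tp + result.fp == len(srcs)
    if result.tp:
        assert result.pairs["diff_days"].abs().max() <= window


@settings(derandomize=True, max_examples=60, deadline=None)
@given(days=st.lists(st.integers(0, 60), min_size=1, max_size=8), window=st.integers(0, 10))
def test_dedup_is_idempotent_and_order_free(days, window):
    epoch = pd.Timestamp("2000-01-01")
    records = pd.DataFrame(
        {
            "record_id": [f"R{i}" for i in range(len(days))],
            "source": "CORR",
            "patient_key": "P1",
            "event_date": [epoch + pd.Timedelta(days=d) for d in days],
            "organ": "kidney",
        }
    )
    once = dedup_source(records, window)
    twice = dedup_source(once, window)
    pd.testing.assert_frame_equal(once, twice)
    shuffled = dedup_source(records.iloc[::-1], window)
    assert list(shuffled["event_date"]) == list(once["event_date"])


def test_perfect_recovery_on_unambiguous_synthetic_data():
    """With jitter capped at the window and false positives >= 30 days out,
    matched pairs are exactly the captured true events."""
    cfg = SimulationConfig(
        n_patients=250, duplicate_rate=0.0, exclusion_fractions={}, seed=31
    ).validate()
    events, _, sources, truth = simulate_study(cfg)
    for source in cfg.sources:
        sub = dedup_source(sources[sources["source"] == source], 7)
        result = match_events(events, sub, 7)
        captured_keys = set(
            truth.loc[(truth["source"] == source) & (truth["kind"] == "captured"), "patient_key"]
        )
        assert result.tp == len(captured_keys)
        assert set(result.pairs["patient_key"]) == captured_keys
        fp_ids = set(
            truth.loc[(truth["source"] == source) & (truth["kind"] == "false_positive"), "record_id"]
        )
        assert set(result.unmatched_source["record_id"]) <= fp_ids


def test_match_by_organ_filters_and_validates(ref_frame, src_frame):
    refs = ref_frame([dict(organ="kidney")])
    srcs = src_frame([dict(organ="kidney")])
    empty = match_by_organ(refs, srcs, 7, organ="lung")
    assert empty.tp == 0 and empty.fn == 0 and empty.fp == 0
    full = match_by_organ(refs, srcs, 7, organ="kidney")
    assert full.tp == 1
    with pytest.raises(ValueError, match="unknown organ"):
        match_by_organ(refs, srcs, 7, organ="pancreas")


def test_mislabeled_source_organ_stays_in_its_labeled_stratum(ref_frame, src_frame):
    refs = ref_frame([dict(organ="kidney")])
    srcs = src_frame([dict(organ="liver")])  # mislabeled in the source
    kidney = match_by_organ(refs, srcs, 7, organ="kidney")
    assert kidney.tp == 0 and kidney.fn == 1 and kidney.fp == 0
    liver = match_by_organ(refs, srcs, 7, organ="liver")
    assert liver.tp == 0 and liver.fn == 0 and liver.fp == 1
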