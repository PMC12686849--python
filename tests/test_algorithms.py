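"""Boolean combination semantics and algorithm-level invariants."""

import itertools

import pandas as pd
import pytest

from txvalid import (
    AlgorithmSpec,
    And,
    Leaf,
    Or,
    clean_reference,
    default_registry,
    evaluate_algorithm,
    identified_events,
    parse_expression,
)
from txvalid.algorithms import ContingencyCounts


def test_parser_builds_the_right_trees():
    assert parse_expression("CORR") == Leaf("CORR")
    assert parse_expression("CIHI-DAD-p or CORR") == Or((Leaf("CIHI-DAD-p"), Leaf("CORR")))
    assert parse_expression("CORR and OHIP") == And((Leaf("CORR"), Leaf("OHIP")))
    with pytest.raises(ValueError, match="mixed"):
        parse_expression("CORR and OHIP or CIHI-DAD-p")
    with pytest.raises(ValueError, match="unknown source"):
        parse_expression("CORR or MYSTERY")


def test_default_registry_is_the_ten_algorithms():
    registry = default_registry()
    assert len(registry) == 10
    singles = [a for a in registry if a.is_single_source]
    assert {a.label for a in singles} == {"CORR", "CIHI-DAD-p", "OHIP"}
    assert "CIHI-DAD-p or CORR or OHIP" in {a.label for a in registry}


def test_or_identifies_and_requires_all_sources(src_frame):
    events = src_frame([dict(source="CIHI-DAD-p")])
    or_spec = AlgorithmSpec.from_string("CIHI-DAD-p or CORR")
    and_spec = AlgorithmSpec.from_string("CIHI-DAD-p and CORR")
    assert len(identified_events(or_spec, events, 7)) == 1
    assert len(identified_events(and_spec, events, 7)) == 0


def test_cross_source_merge_fails_beyond_window(src_frame):
    events = src_frame(
        [
            dict(source="CORR", event_date="2005-03-10"),
            dict(source="OHIP", event_date="2005-03-20"),
        ]
    )
    and_spec = AlgorithmSpec.from_string("CORR and OHIP")
    or_spec = AlgorithmSpec.from_string("CORR or OHIP")
    assert len(identified_events(and_spec, events, 7)) == 0
    # the two candidates cannot merge -> two identified events
    assert len(identified_events(or_spec, events, 7)) == 2
    # patient-level AND ignores dates
    assert len(identified_events(and_spec, events, 7, and_mode="patient-level")) == 1


def test_cross_source_merge_takes_earliest_date(src_frame):
    events = src_frame(
        [
            dict(source="CORR", event_date="2005-03-12"),
            dict(source="OHIP", event_date="2005-03-10"),
        ]
    )
    or_spec = AlgorithmSpec.from_string("CORR or OHIP")
    out = identified_events(or_spec, events, 7)
    assert len(out) == 1
    assert out["event_date"].iloc[0] == pd.Timestamp("2005-03-10")
    assert out["sources"].iloc[0] == frozenset({"CORR", "OHIP"})


def test_empty_sources_identify_nothing():
    empty = pd.DataFrame(columns=["record_id", "source", "patient_key", "event_date", "organ"])
    spec = AlgorithmSpec.from_string("CIHI-DAD-p or CORR or OHIP")
    assert len(identified_events(spec, empty, 7)) == 0


def test_unknown_leaf_is_an_error(src_frame):
    events = src_frame([dict()])
    spec = AlgorithmSpec(label="bad", expression=Leaf("NOT-A-SOURCE"))
    with pytest.raises(ValueError, match="unknown sources"):
        identified_events(spec, events, 7)


def test_perfect_single_source_gives_full_sensitivity(ref_frame, src_frame):
    refs = ref_frame([dict(patient_key=f"P{i}", transplant_date=f"2005-03-{i + 1:02d}") for i in range(5)])
    srcs = src_frame(
        [dict(patient_key=f"P{i}", event_date=f"2005-03-{i + 1:02d}") for i in range(5)]
    )
    counts = evaluate_algorithm(AlgorithmSpec.from_string("CORR"), refs, srcs)
    assert (counts.tp, counts.fn, counts.fp) == (5, 0, 0)


@pytest.fixture(scope="module")
def synthetic_run(request):
    from txvalid import SimulationConfig, simulate_study

    cfg = SimulationConfig(n_patients=300, seed=23).validate()
    events, _, sources, _ = simulate_study(cfg)
    eligible, _ = clean_reference(events, cfg.study_window, cfg.center)
    return cfg, eligible, sources


def _sens(counts: ContingencyCounts) -> float:
    return counts.tp / (counts.tp + counts.fn)


def test_monotonicity_invariants_on_synthetic_run(synthetic_run):
    """OR never loses sensitivity relative to its best leaf; AND never beats
    its worst leaf; pairwise AND TP is bounded by each single TP."""
    _, eligible, sources = synthetic_run
    single = {
        lbl: evaluate_algorithm(AlgorithmSpec.from_string(lbl), eligible, sources)
        for lbl in ("CORR", "CIHI-DAD-p", "OHIP")
    }
    for a, b in itertools.combinations(single, 2):
        or_counts = evaluate_algorithm(AlgorithmSpec.from_string(f"{a} or {b}"), eligible, sources)
        and_counts = evaluate_algorithm(AlgorithmSpec.from_string(f"{a} and {b}"), eligible, sources)
        assert _sens(or_counts) >= max(_sens(single[a]), _sens(single[b]))
        assert _sens(and_counts) <= min(_sens(single[a]), _sens(single[b]))
        assert and_counts.tp <= min(single[a].tp, single[b].tp)


def test_or_is_commutative_and_gains_from_extra_leaf(synthetic_run):
    _, eligible, sources = synthetic_run
    ab = evaluate_algorithm(AlgorithmSpec.from_string("CIHI-DAD-p or CORR"), eligible, sources)
    ba = evaluate_algorithm(AlgorithmSpec.from_string("CORR or CIHI-DAD-p"), eligible, sources)
    assert (ab.tp, ab.fn, ab.fp) == (ba.tp, ba.fn, ba.fp)
    abc = evaluate_algorithm(
        AlgorithmSpec.from_string("CIHI-DAD-p or CORR or OHIP"), eligible, sources
    )
    assert abc.tp >= ab.tp
    # and adding a leaf to an AND never increases TP
    and_ab = evaluate_algorithm(AlgorithmSpec.from_string("CIHI-DAD-p and CORR"), eligible, sources)
    and_abc = evaluate_algorithm(
        AlgorithmSpec(
            label="triple and",
            expression=And((Leaf("CIHI-DAD-p"), Leaf("CORR"), Leaf("OHIP"))),
        ),
        eligible,
        sources,
    )
    assert and_abc.tp <= and_ab.tp


def test_tp_plus_fn_equals_eligible_in_every_stratum(synthetic_run):
    cfg, eligible, sources = synthetic_run
    for organ in ("all", "kidney", "liver"):
        n_stratum = len(eligible) if organ == "all" else (eligible["organ"] == organ).sum()
        for spec in default_registry():
            counts = evaluate_algorithm(spec, eligible, sources, organ=organ)
            assert counts.tp + counts.fn == n_stratum
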