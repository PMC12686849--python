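"""Synthetic reference cohort and administrative source records.

The generator produces two tables with a known ground truth so every
downstream stage (cohort cleaning, linkage, algorithm evaluation, accuracy
estimation) can be tested and parameter recovery verified:

``reference`` — one row per transplant event at the reference center
    (patient key, transplant date, organ, demographics).  A configurable
    fraction of patients carries an exclusion-triggering attribute (adult
    at transplant, non-resident, repeat transplant, same-day second organ,
    death on/before entry, blanked patient key).

``sources`` — administrative records.  Each true event is captured by each
    source with a probability that may differ before/after the coding-era
    boundary; captured dates get a small truncated-normal jitter rounded to
    whole days; captured events may emit duplicate rows; false-positive
    records are injected at dates at least 30 days away from any true event
    of the same patient, so their classification is unambiguous.

Everything is deterministic given ``config.seed``.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .config import EXCLUSION_REASONS, ConfigError, SimulationConfig

__all__ = [
    "generate_reference_cohort",
    "generate_source_records",
    "simulate_study",
    "era_of",
]

#: Minimum gap (days) between an injected false positive and any true event
#: of the same patient.  Keeps ground-truth FP/TP classification unambiguous
#: for any matching window up to this gap.
FP_MIN_GAP_DAYS = 30

_DAYS_PER_YEAR = 365.25


def era_of(event_date, boundary: date) -> str:
    """Coding era of a date: 'post' on/after the boundary, else 'pre'."""
    ts = pd.Timestamp(event_date)
    return "post" if ts >= pd.Timestamp(boundary) else "pre"


def _random_dates(rng: np.random.Generator, start: date, end: date, n: int) -> pd.Series:
    span = (pd.Timestamp(end) - pd.Timestamp(start)).days
    offsets = rng.integers(0, span + 1, size=n)
    return pd.Series(pd.Timestamp(start) + pd.to_timedelta(offsets, unit="D"))


def generate_reference_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the reference-standard transplant events and patient table.

    Returns
    -------
    events : DataFrame
        Columns ``patient_key, transplant_date, organ, birth_date, sex,
        resident, death_date, center``; one row per transplant event
        (patients with injected repeat or same-day multi-organ transplants
        contribute two rows).
    patients : DataFrame
        One row per patient with demographics and the injected
        ``exclusion_reason`` ('' when none) — ground truth for testing the
        exclusion cascade.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    start, end = config.study_window

    keys = np.array([f"P{i:06d}" for i in range(1, n + 1)], dtype=object)
    organs = list(config.organ_probs)
    organ = rng.choice(organs, size=n, p=[config.organ_probs[o] for o in organs])
    tx_date = _random_dates(rng, start, end, n)
    # pediatric ages: uniform over [0, 18) years at transplant
    age_days = rng.uniform(0.0, 18.0 * _DAYS_PER_YEAR, size=n)
    birth_date = tx_date - pd.to_timedelta(np.floor(age_days).astype(int), unit="D")
    sex = rng.choice(["F", "M"], size=n)
    resident = np.ones(n, dtype=bool)
    death_date = pd.Series(pd.NaT, index=range(n))

    # categorical exclusion assignment: each patient draws at most one reason
    reasons = [r for r in EXCLUSION_REASONS]
    probs = np.array([config.exclusion_fractions.get(r, 0.0) for r in reasons])
    u = rng.random(n)
    cut = np.concatenate([[0.0], np.cumsum(probs)])
    assigned = np.full(n, "", dtype=object)
    for i, r in enumerate(reasons):
        assigned[(u >= cut[i]) & (u < cut[i + 1])] = r

    extra_rows = []
    for i in np.flatnonzero(assigned != ""):
        reason = assigned[i]
        if reason == "adult":
            adult_days = rng.uniform(18.0, 26.0) * _DAYS_PER_YEAR
            birth_date.iloc[i] = tx_date.iloc[i] - pd.Timedelta(days=int(adult_days))
        elif reason == "non_resident":
            resident[i] = False
        elif reason == "repeat_transplant":
            # move the first event early enough to leave room for a second
            first_span = max((pd.Timestamp(end) - pd.Timestamp(start)).days - 365, 1)
            tx_date.iloc[i] = pd.Timestamp(start) + pd.Timedelta(
                days=int(rng.integers(0, first_span))
            )
            birth_date.iloc[i] = tx_date.iloc[i] - pd.Timedelta(days=int(age_days[i]))
            room = (pd.Timestamp(end) - tx_date.iloc[i]).days
            second = tx_date.iloc[i] + pd.Timedelta(days=int(rng.integers(30, room + 1)))
            extra_rows.append(
                dict(
                    patient_key=keys[i],
                    transplant_date=second,
                    organ=rng.choice(organs, p=[config.organ_probs[o] for o in organs]),
                    _row_kind="repeat",
                    _patient_idx=i,
                )
            )
        elif reason == "multi_organ_same_day":
            other = [o for o in organs if o != organ[i]]
            extra_rows.append(
                dict(
                    patient_key=keys[i],
                    transplant_date=tx_date.iloc[i],
                    organ=rng.choice(other),
                    _row_kind="multi_organ",
                    _patient_idx=i,
                )
            )
        elif reason == "death_on_entry":
            death_date.iloc[i] = tx_date.iloc[i] - pd.Timedelta(days=int(rng.integers(0, 30)))
        elif reason == "missing_key":
            keys[i] = ""

    patients = pd.DataFrame(
        {
            "patient_key": keys,
            "birth_date": birth_date.values,
            "sex": sex,
            "resident": resident,
            "death_date": death_date.values,
            "exclusion_reason": assigned,
        }
    )

    events = pd.DataFrame(
        {
            "patient_key": keys,
            "transplant_date": tx_date.values,
            "organ": organ,
            "birth_date": birth_date.values,
            "sex": sex,
            "resident": resident,
            "death_date": death_date.values,
            "center": config.center,
        }
    )
    if extra_rows:
        extras = pd.DataFrame(extra_rows)
        idx = extras.pop("_patient_idx").astype(int)
        extras.pop("_row_kind")
        extras["birth_date"] = birth_date.iloc[idx].values
        extras["sex"] = sex[idx]
        extras["resident"] = resident[idx]
        extras["death_date"] = death_date.iloc[idx].values
        extras["center"] = config.center
        events = pd.concat([events, extras[events.columns]], ignore_index=True)

    events = events.sort_values(
        ["patient_key", "transplant_date", "organ"], kind="mergesort"
    ).reset_index(drop=True)
    return events, patients


def generate_source_records(
    cohort: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit administrative source records for the given reference events.

    Parameters
    ----------
    cohort : DataFrame
        Reference events (typically the eligible cohort) with columns
        ``patient_key, transplant_date, organ``.
    config : SimulationConfig

    Returns
    -------
    sources : DataFrame
        Columns ``record_id, source, patient_key, event_date, organ``.
    ground_truth : DataFrame
        One row per emitted record: ``record_id, source, kind`` (one of
        ``captured``, ``duplicate``, ``false_positive``), ``patient_key,
        true_date, offset_days``.  Every record carries exactly one tag.
    """
    config.validate()
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    start, end = config.study_window

    events = cohort.reset_index(drop=True)
    eras = np.array(
        [era_of(d, config.era_boundary) for d in events["transplant_date"]], dtype=object
    )
    true_dates_by_patient = (
        events.groupby("patient_key")["transplant_date"].apply(list).to_dict()
    )
    valid_keys = np.array(
        sorted(k for k in events["patient_key"].unique() if isinstance(k, str) and k),
        dtype=object,
    )

    def jitter(size: int) -> np.ndarray:
        if config.jitter_sd_days == 0:
            return np.zeros(size, dtype=int)
        raw = rng.normal(0.0, config.jitter_sd_days, size=size)
        raw = np.clip(raw, -config.jitter_max_days, config.jitter_max_days)
        return np.rint(raw).astype(int)

    src_rows: list[dict] = []
    truth_rows: list[dict] = []

    def emit(source, key, event_date, organ, kind, true_date, offset):
        rid = f"R{len(src_rows) + 1:06d}"
        src_rows.append(
            dict(record_id=rid, source=source, patient_key=key,
                 event_date=event_date, organ=organ)
        )
        truth_rows.append(
            dict(record_id=rid, source=source, kind=kind, patient_key=key,
                 true_date=true_date, offset_days=offset)
        )

    n_events = len(events)
    for source in config.sources:
        p = np.array([config.capture_for(source, e) for e in eras])
        captured = rng.random(n_events) < p
        offsets = jitter(n_events)
        dup = rng.random(n_events) < config.duplicate_rate
        dup_offsets = jitter(n_events)
        for i in np.flatnonzero(captured):
            true_date = events["transplant_date"].iloc[i]
            key = events["patient_key"].iloc[i]
            organ = events["organ"].iloc[i]
            emit(source, key, true_date + pd.Timedelta(days=int(offsets[i])),
                 organ, "captured", true_date, int(offsets[i]))
            if dup[i]:
                emit(source, key, true_date + pd.Timedelta(days=int(dup_offsets[i])),
                     organ, "duplicate", true_date, int(dup_offsets[i]))

        # injected false positives: far from every true event of the patient
        n_fp = int(rng.poisson(config.fp_rate_for(source) * n_events))
        organs = list(config.organ_probs)
        organ_p = [config.organ_probs[o] for o in organs]
        for _ in range(n_fp):
            if len(valid_keys) == 0:
                break
            for _attempt in range(200):
                key = rng.choice(valid_keys)
                cand = _random_dates(rng, start, end, 1).iloc[0]
                gaps = [abs((cand - t).days) for t in true_dates_by_patient.get(key, [])]
                if all(g >= FP_MIN_GAP_DAYS for g in gaps):
                    emit(source, key, cand, rng.choice(organs, p=organ_p),
                         "false_positive", pd.NaT, np.nan)
                    break

    columns = ["record_id", "source", "patient_key", "event_date", "organ"]
    truth_cols = ["record_id", "source", "kind", "patient_key", "true_date", "offset_days"]
    sources = pd.DataFrame(src_rows, columns=columns)
    ground_truth = pd.DataFrame(truth_rows, columns=truth_cols)
    sources["event_date"] = pd.to_datetime(sources["event_date"])
    ground_truth["true_date"] = pd.to_datetime(ground_truth["true_date"])
    return sources, ground_truth


def simulate_study(config: SimulationConfig):
    """Full generator pass: reference events, patient table, sources, truth."""
    events, patients = generate_reference_cohort(config)
    sources, truth = generate_source_records(events, config)
    return events, patients, sources, truth
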