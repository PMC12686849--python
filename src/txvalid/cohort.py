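"""Reference-cohort cleaning and exclusion cascade.

The eligible cohort — the sensitivity denominator — is produced by applying
data-cleaning and exclusion rules in a fixed, documented order.  Each event
is excluded under the *first* applicable reason, so the ledger counts are
reproducible and sum (with the eligible count) to the input size.

Order of application:

1.  missing or invalid patient key (blank / NaN)
2.  unparseable / missing transplant date
3.  missing age (birth date) or sex
4.  death on or before the transplant date
5.  non-resident
6.  aged 18 years or older on the transplant date (attained whole years)
7.  simultaneous multi-organ transplant (two different organs on the same
    calendar date) — the patient is excluded outright
8.  exact duplicate rows (same patient, date, organ) — deduplicated, counted
9.  repeat transplant — each patient restricted to the earliest event
    (date ties broken by organ name, alphabetically)
10. transplant date outside the study window
11. surgery not performed at the reference center
12. organ not one of kidney / liver / heart / lung
"""

from __future__ import annotations

from datetime import date

import pandas as pd

from .config import ORGANS

__all__ = ["EXCLUSION_ORDER", "age_years", "clean_reference"]

EXCLUSION_ORDER: tuple[str, ...] = (
    "missing_or_invalid_key",
    "invalid_transplant_date",
    "missing_age_or_sex",
    "death_on_or_before_entry",
    "non_resident",
    "age_18_or_older",
    "simultaneous_multi_organ",
    "duplicate_row",
    "repeat_transplant",
    "outside_study_window",
    "non_center_surgery",
    "organ_not_recognized",
)


def age_years(birth_date, on_date) -> int:
    """Attained age in whole years on ``on_date`` (floor convention)."""
    b, d = pd.Timestamp(birth_date), pd.Timestamp(on_date)
    years = d.year - b.year
    if (d.month, d.day) < (b.month, b.day):
        years -= 1
    return years


def clean_reference(
    events: pd.DataFrame,
    study_window: tuple[date, date],
    center_name: str = "SickKids",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the exclusion cascade; return (eligible events, exclusion ledger).

    Parameters
    ----------
    events : DataFrame
        Reference events with columns ``patient_key, transplant_date, organ,
        birth_date, sex, resident, death_date, center``.
    study_window : (date, date)
        Inclusive bounds on eligible transplant dates.
    center_name : str
        Events from any other center are excluded.

    Returns
    -------
    eligible : DataFrame
        One event per patient, same columns as the input.
    ledger : DataFrame
        Columns ``reason, count`` in cascade order (every reason present,
        zero counts included).  ``eligible + ledger.count.sum()`` equals the
        input row count.
    """
    if len(events) == 0:
        raise ValueError("events must be nonempty")
    df = events.copy().reset_index(drop=True)
    df["transplant_date"] = pd.to_datetime(df["transplant_date"], errors="coerce")
    df["birth_date"] = pd.to_datetime(df["birth_date"], errors="coerce")
    df["death_date"] = pd.to_datetime(df["death_date"], errors="coerce")

    counts = {reason: 0 for reason in EXCLUSION_ORDER}

    def drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        counts[reason] += int(mask.sum())
        df = df[~mask]

    key = df["patient_key"]
    drop(key.isna() | (key.astype(str).str.strip() == ""), "missing_or_invalid_key")
    drop(df["transplant_date"].isna(), "invalid_transplant_date")
    sex = df["sex"]
    drop(
        df["birth_date"].isna() | sex.isna() | (sex.astype(str).str.strip() == ""),
        "missing_age_or_sex",
    )
    drop(
        df["death_date"].notna() & (df["death_date"] <= df["transplant_date"]),
        "death_on_or_before_entry",
    )
    drop(~df["resident"].astype(bool), "non_resident")
    if len(df):
        ages = df.apply(lambda r: age_years(r["birth_date"], r["transplant_date"]), axis=1)
        drop(ages >= 18, "age_18_or_older")

    # simultaneous multi-organ: >1 distinct organ on one date -> patient excluded
    if len(df):
        multi = df.groupby(["patient_key", "transplant_date"])["organ"].transform("nunique") > 1
        bad_patients = set(df.loc[multi, "patient_key"])
        drop(df["patient_key"].isin(bad_patients), "simultaneous_multi_organ")

    before = len(df)
    df = df.drop_duplicates(subset=["patient_key", "transplant_date", "organ"])
    counts["duplicate_row"] += before - len(df)

    # first transplant per patient; date ties broken by organ name
    if len(df):
        df = df.sort_values(["patient_key", "transplant_date", "organ"], kind="mergesort")
        first = ~df.duplicated(subset="patient_key", keep="first")
        drop(~first, "repeat_transplant")

    start, end = (pd.Timestamp(study_window[0]), pd.Timestamp(study_window[1]))
    drop((df["transplant_date"] < start) | (df["transplant_date"] > end), "outside_study_window")
    drop(df["center"].astype(str) != str(center_name), "non_center_surgery")
    drop(~df["organ"].isin(ORGANS), "organ_not_recognized")

    ledger = pd.DataFrame(
        {"reason": list(EXCLUSION_ORDER), "count": [counts[r] for r in EXCLUSION_ORDER]}
    )
    eligible = df.sort_values("patient_key", kind="mergesort").reset_index(drop=True)
    assert len(eligible) + int(ledger["count"].sum()) == len(events)
    return eligible, ledger
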