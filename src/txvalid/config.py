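"""Simulation configuration for the synthetic transplant-ascertainment study.

The synthetic generator emulates a two-decade pediatric transplant cohort
linked against four administrative sources: a national organ replacement
registry (CORR, voluntary submissions), hospital discharge-abstract
procedural and diagnostic codes (CIHI-DAD-p / CIHI-DAD-d, mandatory
reporting), and provincial physician billing claims (OHIP).  Capture
probabilities may change at a coding-regime boundary (the ICD-9/CCP to
ICD-10/CCI switch on 2002-04-01), which is why ``capture`` is keyed by
``(source, era)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date
from typing import Mapping

__all__ = [
    "SOURCES",
    "ORGANS",
    "ERAS",
    "EXCLUSION_REASONS",
    "ConfigError",
    "SimulationConfig",
]

#: Recognized administrative source identifiers.  The registry is extensible:
#: a SimulationConfig may introduce additional sources through its ``capture``
#: map and downstream stages treat the source column as opaque labels.
SOURCES: tuple[str, ...] = ("CORR", "CIHI-DAD-p", "CIHI-DAD-d", "OHIP")

ORGANS: tuple[str, ...] = ("kidney", "liver", "heart", "lung")

ERAS: tuple[str, ...] = ("pre", "post")

#: Exclusion mechanisms the generator can inject, in the order the categorical
#: assignment consumes their probabilities.
EXCLUSION_REASONS: tuple[str, ...] = (
    "adult",
    "non_resident",
    "repeat_transplant",
    "multi_organ_same_day",
    "death_on_entry",
    "missing_key",
)


class ConfigError(ValueError):
    """Invalid simulation configuration; ``field`` names the offending entry."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def _default_organ_probs() -> dict[str, float]:
    # Organ mix of the reference cohort: ~42% kidney, 30% liver, 24% heart,
    # 4% lung (the small lung share absorbs rounding so the mix sums to 1).
    return {"kidney": 0.42, "liver": 0.30, "heart": 0.24, "lung": 0.04}


def _default_capture() -> dict[tuple[str, str], float]:
    # Per-source probability that a true transplant produces a date-aligned
    # record, by coding era.  Hospital procedural codes are near-uniformly
    # strong; billing claims improve sharply after the coding switch;
    # the voluntary registry deteriorates; diagnostic codes almost never
    # align with the surgery date (they appear on later admissions).
    return {
        ("CIHI-DAD-p", "pre"): 0.91,
        ("CIHI-DAD-p", "post"): 0.91,
        ("CORR", "pre"): 0.77,
        ("CORR", "post"): 0.44,
        ("OHIP", "pre"): 0.21,
        ("OHIP", "post"): 0.74,
        ("CIHI-DAD-d", "pre"): 0.005,
        ("CIHI-DAD-d", "post"): 0.005,
    }


def _default_fp_rate() -> dict[str, float]:
    # Expected false-positive events per source as a fraction of true events.
    # Chosen so single-source PPV sits in the low-to-mid 90s; the diagnostic-
    # code source emits many records detached from the surgery date.
    return {
        "CIHI-DAD-p": 0.069,
        "CORR": 0.038,
        "OHIP": 0.050,
        "CIHI-DAD-d": 0.79,
    }


def _default_exclusions() -> dict[str, float]:
    return {
        "adult": 0.02,
        "non_resident": 0.02,
        "repeat_transplant": 0.05,
        "multi_organ_same_day": 0.005,
        "death_on_entry": 0.005,
        "missing_key": 0.01,
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one synthetic study.

    Parameters
    ----------
    n_patients
        Number of patients generated (before exclusion cascade).
    organ_probs
        Map organ -> probability; must sum to 1.
    capture
        Map (source, era) -> probability that a true transplant event emits a
        date-aligned record in that source, era in {"pre", "post"} relative
        to ``era_boundary``.
    fp_rate
        Expected false positives per source as a fraction of true events.
        Either one scalar for every source or a map source -> rate.
    jitter_sd_days
        Standard deviation (days) of the normal date jitter added to emitted
        records, truncated at ``jitter_max_days`` and rounded to whole days.
    duplicate_rate
        Probability a captured event emits a second (duplicate) record.
    exclusion_fractions
        Map exclusion reason -> probability a patient carries that
        exclusion-triggering attribute; reasons are mutually exclusive and
        their probabilities must sum to at most 1.
    era_boundary
        Calendar date splitting "pre" from "post"; the boundary date itself
        belongs to the post era (conventional for a fiscal-year start).
    study_window
        (start, end) of transplant dates, inclusive.
    seed
        Seed for all randomness in the generator.
    """

    n_patients: int = 825
    organ_probs: Mapping[str, float] = field(default_factory=_default_organ_probs)
    capture: Mapping[tuple[str, str], float] = field(default_factory=_default_capture)
    fp_rate: float | Mapping[str, float] = field(default_factory=_default_fp_rate)
    jitter_sd_days: float = 0.4
    jitter_max_days: int = 7
    duplicate_rate: float = 0.05
    exclusion_fractions: Mapping[str, float] = field(default_factory=_default_exclusions)
    era_boundary: date = date(2002, 4, 1)
    study_window: tuple[date, date] = (date(1991, 7, 1), date(2011, 12, 31))
    seed: int = 0
    center: str = "SickKids"

    # -- derived helpers ---------------------------------------------------
    @property
    def sources(self) -> tuple[str, ...]:
        """Sources appearing in the capture map, in registry-then-alpha order."""
        found = {src for (src, _era) in self.capture}
        known = [s for s in SOURCES if s in found]
        extra = sorted(found - set(SOURCES))
        return tuple(known + extra)

    def fp_rate_for(self, source: str) -> float:
        if isinstance(self.fp_rate, Mapping):
            return float(self.fp_rate.get(source, 0.0))
        return float(self.fp_rate)

    def capture_for(self, source: str, era: str) -> float:
        return float(self.capture.get((source, era), 0.0))

    def validate(self) -> "SimulationConfig":
        """Check invariants; raise :class:`ConfigError` naming the bad field."""
        if not (isinstance(self.n_patients, int) and self.n_patients > 0):
            raise ConfigError("n_patients", "must be a positive integer")
        total = 0.0
        for organ, p in self.organ_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError("organ_probs", f"probability for {organ!r} outside [0, 1]")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise ConfigError("organ_probs", f"must sum to 1 (got {total!r})")
        for (src, era), p in self.capture.items():
            if era not in ERAS:
                raise ConfigError("capture", f"unknown era {era!r} for source {src!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError("capture", f"probability for ({src!r}, {era!r}) outside [0, 1]")
        rates = (
            self.fp_rate.values() if isinstance(self.fp_rate, Mapping) else [self.fp_rate]
        )
        for r in rates:
            if r < 0:
                raise ConfigError("fp_rate", "must be >= 0")
        if self.jitter_sd_days < 0:
            raise ConfigError("jitter_sd_days", "must be >= 0")
        if self.jitter_max_days < 0:
            raise ConfigError("jitter_max_days", "must be >= 0")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ConfigError("duplicate_rate", "must be in [0, 1]")
        excl_total = 0.0
        for reason, p in self.exclusion_fractions.items():
            if reason not in EXCLUSION_REASONS:
                raise ConfigError("exclusion_fractions", f"unknown reason {reason!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError("exclusion_fractions", f"probability for {reason!r} outside [0, 1]")
            excl_total += p
        if excl_total > 1.0 + 1e-9:
            raise ConfigError("exclusion_fractions", "probabilities sum to more than 1")
        start, end = self.study_window
        if not start < end:
            raise ConfigError("study_window", "start must precede end")
        if not (start <= self.era_boundary <= end):
            raise ConfigError("era_boundary", "must lie within the study window")
        return self

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **kwargs).validate()

    def to_dict(self) -> dict:
        """JSON/YAML-serializable form (capture keyed ``source: {era: p}``)."""
        capture: dict[str, dict[str, float]] = {}
        for (src, era), p in self.capture.items():
            capture.setdefault(src, {})[era] = p
        return {
            "n_patients": self.n_patients,
            "organ_probs": dict(self.organ_probs),
            "capture": capture,
            "fp_rate": dict(self.fp_rate) if isinstance(self.fp_rate, Mapping) else self.fp_rate,
            "jitter_sd_days": self.jitter_sd_days,
            "jitter_max_days": self.jitter_max_days,
            "duplicate_rate": self.duplicate_rate,
            "exclusion_fractions": dict(self.exclusion_fractions),
            "era_boundary": self.era_boundary.isoformat(),
            "study_window": [d.isoformat() for d in self.study_window],
            "seed": self.seed,
            "center": self.center,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        kwargs = dict(data)
        if "capture" in kwargs:
            flat: dict[tuple[str, str], float] = {}
            for src, eras in kwargs["capture"].items():
                for era, p in eras.items():
                    flat[(src, era)] = float(p)
            kwargs["capture"] = flat
        if "era_boundary" in kwargs and isinstance(kwargs["era_boundary"], str):
            kwargs["era_boundary"] = date.fromisoformat(kwargs["era_boundary"])
        if "study_window" in kwargs:
            s, e = kwargs["study_window"]
            kwargs["study_window"] = (
                date.fromisoformat(s) if isinstance(s, str) else s,
                date.fromisoformat(e) if isinstance(e, str) else e,
            )
        return cls(**kwargs).validate()
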