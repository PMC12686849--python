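from datetime import date

import pandas as pd
import pytest

from txvalid import SimulationConfig, simulate_study

STUDY_WINDOW = (date(1991, 7, 1), date(2011, 12, 31))


def _dates(df, cols):
    for c in cols:
        if c in df.columns:
            df[c] = pd.to_datetime(df[c])
    return df


@pytest.fixture
def ref_frame():
    """Factory for small reference-event tables with sensible defaults."""

    def make(rows):
        defaults = dict(
            patient_key="P1",
            transplant_date="2001-05-01",
            organ="kidney",
            birth_date="1995-01-01",
            sex="F",
            resident=True,
            death_date=None,
            center="SickKids",
        )
        df = pd.DataFrame([{**defaults, **r} for r in rows])
        return _dates(df, ["transplant_date", "birth_date", "death_date"])

    return make


@pytest.fixture
def src_frame():
    """Factory for small source-record tables."""

    def make(rows):
        defaults = dict(source="CORR", patient_key="P1", event_date="2001-05-01", organ="kidney")
        df = pd.DataFrame([{**defaults, **r} for r in rows])
        df.insert(0, "record_id", [f"R{i + 1:06d}" for i in range(len(df))])
        return _dates(df, ["event_date"])

    return make


#: Era-invariant capture at the overall per-source sensitivities, with
#: false-positive rates set for low-90s PPV; no exclusions, so the eligible
#: cohort is exactly n_patients.
RECOVERY_CONFIG = SimulationConfig(
    n_patients=825,
    capture={
        ("CIHI-DAD-p", "pre"): 0.91,
        ("CIHI-DAD-p", "post"): 0.91,
        ("CORR", "pre"): 0.59,
        ("CORR", "post"): 0.59,
        ("OHIP", "pre"): 0.51,
        ("OHIP", "post"): 0.51,
    },
    fp_rate={"CIHI-DAD-p": 0.069, "CORR": 0.038, "OHIP": 0.050},
    exclusion_fractions={},
    seed=11,
)


@pytest.fixture(scope="session")
def recovery_study():
    cfg = RECOVERY_CONFIG.validate()
    events, patients, sources, truth = simulate_study(cfg)
    return cfg, events, patients, sources, truth
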