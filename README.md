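# txvalid

Validation toolkit for case-ascertainment algorithms that identify
pediatric solid-organ transplant recipients in administrative health data.

## The problem

Administrative databases — hospital discharge abstracts (procedural codes,
CIHI-DAD-p; diagnostic codes, CIHI-DAD-d), physician billing claims (OHIP),
and a voluntary organ replacement registry (CORR) — are attractive for
population-level transplant research, but only if the codes actually find
the transplants. Validation compares each candidate *ascertainment
algorithm* (a single source, or an OR/AND combination of sources) against a
reference standard of chart-abstracted transplant-center records, linked by
a unique patient key.

For an algorithm A evaluated against a reference cohort of N first
transplants:

- **sensitivity** = TP / (TP + FN): the probability a reference-standard
  transplant is identified by A;
- **PPV** = TP / (TP + FP): the probability an A-identified event is a true
  transplant.

A reference event and an administrative event count as concordant (TP) when
the patient keys agree and the dates lie within ±7 days. Specificity and
NPV are undefined by design — the frame has no enumerable true-negative
pool. Estimates carry 95% Wilson score intervals, and any contributing cell
with a count strictly between 0 and 6 is suppressed (rendered `<6`), the
standard privacy rule of health-data custodians.

Because the real linked data are access-restricted, the package ships a
synthetic-data generator with known ground truth (per-source,
per-coding-era capture probabilities; date jitter; duplicates; injected
false positives; exclusion-triggering patients), so the full pipeline —
exclusion cascade, date-window linkage, Boolean algorithm evaluation,
stratified accuracy, date concordance — is testable end to end and
parameter recovery can be verified.

## Worked example

```python
from txvalid import SimulationConfig, simulate_study, run_validation

cfg = SimulationConfig(seed=1).validate()          # defaults emulate the study
events, patients, sources, truth = simulate_study(cfg)
run = run_validation(events, sources, cfg.study_window, config=cfg.to_dict(), seed=1)
print(run.report.tables[("all", "all")].to_string(index=False))
```

prints

```
                 algorithm sensitivity         ppv
CIHI-DAD-p or CORR or OHIP 98% (97-99) 76% (73-78)
        CIHI-DAD-p or CORR 96% (94-97) 78% (76-81)
        CIHI-DAD-p or OHIP 95% (94-97) 78% (76-81)
                CIHI-DAD-p 90% (88-92) 81% (78-84)
              CORR or OHIP 85% (83-88) 81% (78-84)
                      CORR 62% (58-65) 85% (81-87)
       CIHI-DAD-p and CORR 56% (52-59) 91% (88-93)
                      OHIP 50% (47-54) 81% (78-85)
       CIHI-DAD-p and OHIP 45% (41-48) 88% (85-91)
             CORR and OHIP 26% (23-30) 89% (85-93)
```

Each row is one algorithm, ranked by sensitivity then PPV, as `estimate%
(95% CI)`. Hospital procedural codes dominate the single sources (90%
sensitivity here, against a configured capture of 0.91); OR combinations
buy sensitivity at the cost of PPV, AND combinations the reverse. In this
default study the capture probabilities are era-dependent and excluded
patients' records remain in the administrative stream, so single-source PPV
sits below the no-exclusion recovery setting — exactly the kind of
contamination a validation study is meant to surface.

The `examples/` directory walks through each capability: simulation and
ground truth (`01`), the exclusion cascade (`02`), algorithm evaluation
(`03`), era stratification (`04`), and date concordance (`05`). A thin CLI
mirrors the shell workflow:

```bash
txvalid simulate --out study/ --seed 1
txvalid validate --reference study/reference.csv --sources study/sources.csv --out results/
txvalid report --in results/
```

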