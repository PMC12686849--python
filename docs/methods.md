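# Methods

## Study design being modeled

The package implements the analysis pipeline of a diagnostic-accuracy
validation study: a reference standard of chart-abstracted pediatric
solid-organ transplants (kidney, liver, heart, lung; first transplants
only) from a single transplant center over 1991-07-01 to 2011-12-31, linked
by an exact patient key to four administrative sources — hospital
discharge-abstract procedural codes (CIHI-DAD-p) and diagnostic codes
(CIHI-DAD-d), a voluntary organ replacement registry (CORR), and physician
billing claims (OHIP). Ten algorithms are evaluated: the three usable
single sources, six pairwise OR/AND combinations, and the triple OR.

Sensitivity is TP/(TP+FN) over the eligible reference cohort; PPV is
TP/(TP+FP) over algorithm-identified events. True negatives are undefined
(there is no enumerable non-transplant pool), so specificity and NPV are
out of scope, as is any multiple-testing adjustment (none is performed).

## Synthetic data generator

The generator produces the study's two tables with known ground truth.
What it emulates, with defaults:

| parameter | default | rationale |
|---|---|---|
| `n_patients` | 825 | reference cohort size |
| `organ_probs` | kidney .42, liver .30, heart .24, lung .04 | observed organ mix; lung absorbs rounding so the mix sums to 1 |
| `capture[(src, era)]` | DAD-p .91/.91, CORR .77/.44, OHIP .21/.74, DAD-d .005/.005 | per-source probability a true event yields a date-aligned record, pre/post the 2002-04-01 coding switch; billing improved ~3.5-fold, the voluntary registry deteriorated, procedural codes were stable, diagnostic codes almost never align with the surgery date |
| `fp_rate` | DAD-p .069, CORR .038, OHIP .050, DAD-d .79 | expected false positives as a fraction of true events, derived once from printed sensitivity/PPV pairs via FP = TP·(1/PPV − 1); DAD-d's large rate reproduces a source with many records detached from the transplant date |
| `jitter_sd_days` | 0.4 | date jitter SD, truncated at ±`jitter_max_days` (7) and rounded to whole days; gives mean absolute differences ≈ 0.2 d and median 0 (IQR 0–0), the observed regime |
| `duplicate_rate` | 0.05 | probability a captured event emits a second record |
| `exclusion_fractions` | adult .02, non-resident .02, repeat .05, same-day multi-organ .005, death-on-entry .005, missing key .01 | illustrative; the real cascade counts are not public at this granularity |

Design choices worth stating:

- **Jitter distribution.** Only its consequences are observable (tight
  means/SDs, zero medians), so the form is a modeling choice: a truncated
  rounded normal — small, symmetric, mostly zero.
- **False-positive placement.** Injected FPs land ≥ 30 days from every true
  event of the assigned patient. This makes ground-truth classification
  unambiguous for any matching window up to 30 days and is why
  "matched pairs = captured events" holds exactly on unambiguous fixtures.
- **Eras.** An event is "post" when its true date is on or after the
  boundary — the conventional reading of a fiscal-year start.
- **Missing keys** are blanked, not dropped, so the cleaning stage has
  something to remove.

What the generator does *not* emulate: actual ICD/CCP/CCI code strings (a
record simply exists in a source or not), inter-provincial migration,
center-level reporting idiosyncrasies, or correlation between sources'
capture indicators (captures are independent given the event). Passing
recovery tests therefore shows the *pipeline* is unbiased under the stated
mechanism, not that the mechanism exhausts real administrative data.

## Exclusion cascade

Rules apply in a fixed order (first applicable reason wins), so the ledger
is reproducible: invalid key → unparseable date → missing age/sex → death
on/before entry → non-resident → age ≥ 18 (attained whole years; exactly 18
is excluded) → simultaneous multi-organ (two different organs the same day
excludes the patient) → exact-duplicate rows (deduplicated, counted) →
repeat transplants (first event kept; date ties broken by organ name) →
outside study window → other center → unrecognized organ. The eligible
count plus ledger counts always equals the input row count, and cleaning is
idempotent.

## Linkage

Within-source deduplication clusters records per (source, patient) greedily
in date order, anchored at each cluster's earliest date; the earliest
record represents the cluster. Matching is per patient key and exact:
maximize the number of pairs with |date difference| ≤ window (default 7,
inclusive), then minimize the total absolute difference, then pair earlier
reference events with earlier source events. Candidate sets per patient are
tiny, so exhaustive search is cheap and order-independent. One-to-one
matching is deliberate: letting one record certify two transplants would
inflate TP. Organ agreement is *not* required in the all-organ analysis
(the concordance rule is key + date only); per-organ analyses filter the
source side by its own organ label (a flag allows reference-side-only
filtering instead).

## Boolean algorithms

OR takes the union of the leaves' deduplicated events and merges
same-patient events within the window (same greedy clustering primitive;
merged events keep the earliest date — the "first record" convention). AND
requires every leaf to contribute an event with pairwise date agreement
inside the window (default "date-window" mode); a "patient-level" mode
requiring only co-presence of the patient in all leaves is provided because
record-level AND semantics are underdetermined — reports name the mode
used. These semantics guarantee the monotonicity invariants asserted in the
tests: sens(OR) ≥ max of its leaves, sens(AND) ≤ min, and adding a leaf
never hurts an OR or helps an AND.

## Accuracy, suppression, strata

Intervals are 95% Wilson score by default (good behavior near 0/1 at
per-organ sample sizes), with exact Clopper–Pearson as an option; the
method is recorded per row. Rendered percentages round halves away from
zero; underlying tables keep full precision. Suppression flags any
contributing cell (TP and FN for sensitivity; TP and FP for PPV) strictly
between 0 and the threshold (default 6); zeros are structural and
reportable. A single-source algorithm whose overall sensitivity cell is
suppressed is removed from the ranked report entirely, the way a
diagnostic-code source with under-threshold alignment is dropped from
analysis. The default reporting grid is all-organ and per-organ panels,
plus pre/post-era splits for the full cohort and for kidney (the largest
subgroup). Era strata are assigned after matching — TP/FN by the reference
date, FP by the identified event's own date — so a pair never straddles
strata.

## Date concordance

Signed differences are source minus reference (positive = administrative
date later). Summaries report mean (SD) of signed and absolute differences
and median (25th, 75th percentile) of absolute differences; SDs use the
n−1 denominator and quantiles use linear interpolation between closest
ranks (numpy's default) — stated because the 25th/75th percentile is
convention-dependent. Zero matched pairs yield NaN statistics with
`n_pairs = 0`.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline at the study scale
(825 patients) for recovery checks, 200–400 patients for invariant suites,
and 1000 tiny random instances for the matcher-vs-enumeration oracle; a
full default-study validation takes a few seconds on one core. Every
stochastic component draws from a `numpy` generator seeded from the
user-supplied seed; identical configuration and seed give byte-identical
outputs, and the report embeds a hash of the configuration alongside the
seed.

## Known limitations

- Capture indicators are independent across sources; real sources share
  upstream failure modes (e.g., the same aborted procedure coded in two
  systems).
- False positives are attached to cohort patients only; out-of-cohort
  individuals who would enter via administrative data alone are not
  modeled.
- The exclusion-fraction defaults are illustrative, so ledger counts from
  default runs are not calibrated to any published cascade.
- Record-level AND/OR semantics are a design choice (documented above);
  alternative readings would shift combination-algorithm counts.
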