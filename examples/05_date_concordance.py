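"""Summarize date concordance between administrative and reference dates.

For each source, matched pairs yield signed differences (source minus
reference; positive = administrative date later) and absolute differences;
with small jitter the median absolute difference is 0 days with IQR (0, 0).
"""

from txvalid import SimulationConfig, dedup_source, match_events, simulate_study
from txvalid.reporting import concordance_table, date_concordance

cfg = SimulationConfig(seed=1, exclusion_fractions={}).validate()
events, _, sources, _ = simulate_study(cfg)

summaries = []
for source in cfg.sources:
    sub = dedup_source(sources[sources["source"] == source], 7)
    summaries.append(date_concordance(match_events(events, sub, 7), label=source))

print(concordance_table(summaries).round(3).to_string(index=False))
print(
    "\nmean_signed near 0 = no systematic lag; median_abs 0 with IQR (0, 0) "
    "means most administrative dates agree with the reference to the day."
)
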