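"""Recompute a per-stage sequencing summary from per-run read counts.

The derived cells — stage totals and mapped percentages — are computed from
the raw per-run and mapped counts (in millions) with half-up rounding at one
decimal, the presentation convention of such tables.
"""

from ntrscout import StageSummary
from ntrscout.summary import summary_table

stages = [
    StageSummary("1-cell", [114.4, 52.5, 73.5], mapped_reads=61.9, unique_reads=38.0),
    StageSummary("16-cell", [105.6, 54.4, 85.1], mapped_reads=64.4, unique_reads=39.1),
    StageSummary("512-cell", [109.1, 40.6, 78.4], mapped_reads=76.3, unique_reads=52.9),
    StageSummary("epiboly50", [106.6, 50.8, 78.6], mapped_reads=60.6, unique_reads=36.0),
]

table = summary_table(stages)
print(table.to_string())
print("\ntotal_reads = sum of per-run counts; "
      "mapped_pct = 100 * mapped / total, half-up at one decimal")
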