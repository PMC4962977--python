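"""Quantify called NTRs as FPKM across four developmental stages and derive
fold changes and qualitative profile classes.

Four stage libraries are built from one simulation by keeping, per stage, a
locus-specific fraction of each planted transcript's reads (the simulator's
read provenance says which transcript emitted each read).  This emulates
maternal transcripts decaying toward 50% epiboly, zygotic ones switching on
at the mid-blastula transition (MBT, ~512-cell), and one transcript silent
at 1-cell.  Fold changes use the 1-cell stage as the baseline; the NTR
silent at baseline is flagged undefined rather than given an infinite ratio.
"""

import random

from ntrscout import (
    AnnotationIndex,
    SimConfig,
    expression_matrix,
    fold_change,
    run_discovery,
    scale_rows,
    simulate,
)
from ntrscout.expression import classify_matrix

STAGES = ["1-cell", "16-cell", "512-cell", "epiboly50"]
# per-stage retention of each planted transcript's reads
PATTERNS = {
    "maternal decay": [1.0, 0.7, 0.35, 0.1],
    "MBT peak": [0.15, 0.3, 1.0, 0.4],
    "zygotic (silent at 1-cell)": [0.0, 0.05, 0.3, 1.0],
}

sim = simulate(SimConfig(seed=42))
result = run_discovery(sim.reads, AnnotationIndex(sim.truth.genes))
calls = result.calls[:6]

pattern_names = list(PATTERNS)
assigned = {
    m.transcript_id: pattern_names[i % len(pattern_names)]
    for i, m in enumerate(sim.truth.ntr_models)
}
rng = random.Random(7)
stage_reads = {stage: [] for stage in STAGES}
for read in sim.reads:
    source = sim.truth.read_provenance[read.read_id]
    keep = PATTERNS.get(assigned.get(source), [1.0] * 4)  # genes stay constant
    for stage, frac in zip(STAGES, keep):
        if rng.random() < frac:
            stage_reads[stage].append(read)

matrix = expression_matrix(calls, stage_reads)
print("FPKM (rows: calls, columns: stages):")
print(matrix.fpkm.round(1).to_string())

ratios, undefined = fold_change(matrix, "1-cell")
print("\nfold change vs 1-cell (NaN rows are silent at baseline):")
print(ratios.round(2).to_string())
print("undefined at baseline:", [n for n, u in undefined.items() if u])

print("\nrow-scaled profiles (z per NTR, for heatmap-style clustering):")
print(scale_rows(matrix).round(2).to_string())

print("\nprofile classes:")
print(classify_matrix(matrix, low_threshold=1.0).to_string())
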