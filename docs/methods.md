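# Methods

## Model and assumptions

The discovery procedure is annotation-subtractive and alignment-driven: it
assumes transcription shows up as strand-coherent pileups of uniquely mapped
short reads, that splice junctions extracted from gapped alignments
(reference-skip CIGAR operations) are the most reliable evidence that a
pileup is a processed transcript rather than noise, and that anything near a
known gene is better attributed to that gene than to a novel locus. It makes
no attempt at isoform reconstruction: the unit of discovery is a genomic
region (span plus covered bases plus junction set), not a transcript model.

Coordinates are 0-based half-open everywhere inside the package; GTF and the
printed per-call table are converted at the boundary (1-based inclusive),
BED needs no conversion. Strand is taken from the alignment flag by default,
with an option to prefer a transcription-strand tag (e.g. `XS`) when
present; the method requires an effectively stranded library, since
fragments, clusters and all filters are strand-specific.

"Uniquely mapped" is aligner-dependent; the policy here accepts a read iff
its NH tag equals 1 when the tag is present, otherwise MAPQ ≥ 20. Both knobs
are exposed. Duplicate reads are not removed by default (flagged duplicates
can be skipped via an option).

## Parameters

| parameter | default | meaning |
|---|---|---|
| D1 | 1000 bp | exclusion distance to any same-strand annotated transcript; inclusive boundary (gap = D1 is excluded). Larger D1 lowers the risk of calling extensions of known genes but can hide short transcripts near them. |
| D2 | 5000 bp | maximum gap linking consecutive same-strand fragments into one cluster; inclusive by default with a strict-inequality switch. Larger D2 fuses neighbouring loci; smaller D2 truncates multi-exon loci whose introns exceed it. |
| min_junctions | 2 | distinct splice-junction *sites* (not junction-supporting reads) required to call a cluster. |
| singleton_min_len | 50 bp | junctionless one-fragment clusters longer than this are reported as singletons, never called. The rule is exclusive: a 50 bp cluster is not a singleton. |
| mapq_threshold | 20 | uniqueness fallback when no NH tag is present. |

Two boundary conventions deserve note. Read-to-fragment merging demands a
strictly positive overlap (≥ 1 bp; bookended reads stay apart), whereas
coverage-block merging is bookended-inclusive — the former models
connectivity between reads, the latter the set of transcribed bases.
Fragment connectivity uses the read *span* (introns of spliced reads
included), so a read inside another read's intron joins the same fragment;
this follows from treating a single spliced read as one fragment whose
intron is internal. The D2 linkage boundary is taken as gap ≤ D2 (a strict
switch exists), and the D1 boundary as gap ≤ D1, i.e. "at most D1 away is
excluded".

Secondary-annotation subtraction is an overlap test (≥ 1 bp, same strand),
not a proximity test: it models "was annotated in a later release", an
identity notion, unlike D1 which guards against extensions. Antisense
overlap never removes a fragment or candidate by default
(`same_strand_only`), since a locus antisense to a known gene is still
novel; a strand-agnostic switch exists.

Clusters with ≥ 2 junction sites all contributed by a single read pass the
junction filter; no special case is made. Call ids are assigned in genomic
order under natural chromosome sorting (chr2 before chr10).

## Expression quantification

Reads are assigned to a call by span overlap (≥ 1 bp, same strand), matching
the fragment-connectivity convention; the FPKM length term is the call's
merged covered (exonic) length, and the library size is the stage's
uniquely-mapped read total. This is the plain FPKM definition computed
directly; no parity with any external quantifier's internal normalisation is
claimed. Fold change is a per-row FPKM ratio against the baseline stage;
rows with baseline 0 are flagged undefined and reported as NaN, never as
infinities. Row scaling subtracts the row mean and divides by the sample
standard deviation (n−1 denominator, switchable); constant rows map to zero.
Profile classification applies fixed rules in priority order (post-MBT up →
MBT peak → maternal decay → low flat → other) with a 10% relative tolerance
and a 1-FPKM low threshold; the classes are qualitative descriptions, and
the thresholds are package choices.

The run-summary table rounds derived cells half-up at one decimal (so 0.25 →
0.3), the convention of printed read-count tables; totals are exact sums of
the given per-run inputs.

## Simulator

The generator emulates the targeted study design: stranded 50 bp reads at
20× mean exonic depth over 20 annotated genes (1–4 exons), 10 planted
unannotated 3-exon transcripts, and 3 junctionless decoy spots (80–300 bp)
that exercise the singleton rule. Exon lengths are drawn uniformly from
200–400 bp and intron lengths from 2–4 kb (mean 3 kb, echoing the
approximate mean intron length of the zebrafish genome). Models are shuffled
and placed left to right per chromosome (two 400 kb chromosomes by default)
with inter-model gaps of at least 8 kb, so planted transcripts sit safely
beyond the default D1 and D2 of every gene and of each other; infeasible
placements raise an error naming the constraint. Read start positions are
sampled uniformly along each model's exonic sequence and projected through
the exon structure, so reads crossing exon boundaries become spliced
alignments; `spliced_read_fraction` optionally stratifies sampling between
junction-crossing and non-crossing start positions (the default, None, is
pure positional sampling). Reads carry NH=1 and MAPQ 50 by construction —
the simulator models the post-filter alignment stream, not sequencing error,
multi-mapping, quality strings or coverage biases. Outputs (GTF, coordinate
sorted SAM, truth BED12, truth JSON with read provenance) are byte-identical
for a fixed seed.

What passing recovery tests shows, and does not: at these settings coverage
is deep, junction support is plentiful and loci are well separated, so
precision/recall ≈ 1 demonstrates correctness of the interval logic and
filters, not robustness to shallow or noisy real libraries, overlapping
loci, unstranded protocols or mapping artefacts.

Evaluation matches calls to truth models greedily, one-to-one, by descending
same-strand reciprocal span overlap with a 0.5 threshold; precision is
matched/calls (defined as 1.0 when there are no calls), recall is
matched/truth.

## Numerical and degenerate-input choices

Empty alignment input yields an empty (all-zero) report, an empty GTF a
valid empty index. The annotation distance of a fragment on a chromosome
with no qualifying transcript is "none in range" (None), which the D1 filter
treats as keep. Gap arithmetic is half-open (`next.start − prev.end`), so
bookended features have gap 0. The BED12 score column carries the junction
count capped at 1000 per the format's score range. Junction identity is the
tuple (chrom, intron start, intron end, strand); per-junction read support
is retained for reporting but never collapses distinct sites.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the simulator at its default
conditions (≈ 10⁴ reads per replicate), 20 replicates for recovery, 10 for
the D2 experiment, and 100–200 random instances (≤ 200 elements) for the
brute-force oracle comparisons of fragment building and clustering — sizes
at which the quadratic oracles are exact and fast while exercising all
boundary cases.

## Known limitations

Single-threaded, in-memory processing (fine for the intended desk scale; a
genome-scale run with ~10⁸ reads would need streaming per chromosome).
No coverage-depth thresholds within fragments, no fragment splitting at
coverage dips, no isoform assembly within clusters, no differential-
expression statistics. The expression layer's profile classes assume exactly
four ordered stages.
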