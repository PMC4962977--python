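"""Synthetic stranded RNA-seq over a toy annotated genome, with ground truth.

The generator emulates the study design the discovery workflow targets:
short (50 bp) stranded reads drawn from annotated genes, from planted
unannotated multi-exon transcripts (the truth NTRs), and from a few short
junctionless transcribed spots (decoys that should end up in the singleton
bin, never as calls).  Reads are sampled uniformly along each model's exonic
sequence; a read whose span crosses an exon boundary is emitted as a spliced
alignment with a reference-skip gap.  Every read carries NH=1 — uniqueness
is asserted by construction, since the discovery side consumes post-filter
alignments anyway.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .discovery import NTRCall
from .io_formats import (
    AlignedRead,
    Bed12Record,
    GenomicInterval,
    TranscriptAnnotation,
    natural_chrom_key,
    write_bed12,
    write_gtf,
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome and read sample.

    Defaults follow the emulated design: 50 bp reads at 20x exonic depth over
    20 genes and 10 planted three-exon NTRs; intron lengths average 3 kb (the
    approximate zebrafish genomic mean), and models sit at least
    ``min_gene_gap`` bp apart so planted NTRs are safely beyond the D1/D2
    distances of the discovery defaults.  ``spliced_read_fraction`` is None
    for uniform positional sampling (splicing then follows from where a read
    lands); a number stratifies sampling between junction-crossing and
    non-crossing start positions.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 400_000
    n_genes: int = 20
    n_ntrs: int = 10
    ntr_exons: tuple[int, int] = (3, 3)
    gene_exons: tuple[int, int] = (1, 4)
    exon_length: tuple[int, int] = (200, 400)
    intron_length: tuple[int, int] = (2000, 4000)
    read_length: int = 50
    depth: float = 20.0
    spliced_read_fraction: Optional[float] = None
    min_gene_gap: int = 8000
    decoy_singletons: int = 3
    decoy_length: tuple[int, int] = (80, 300)

    def __post_init__(self) -> None:
        if self.read_length <= 0 or self.depth <= 0:
            raise ValueError("read_length and depth must be positive")
        if min(self.n_chromosomes, self.n_genes, self.n_ntrs,
               self.decoy_singletons) < 0:
            raise ValueError("counts must be non-negative")
        if self.spliced_read_fraction is not None and not (
            0 <= self.spliced_read_fraction <= 1
        ):
            raise ValueError("spliced_read_fraction must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulation: annotated genes, planted NTR models,
    junctionless decoy spots, and the provenance of every emitted read."""

    genes: list[TranscriptAnnotation]
    ntr_models: list[TranscriptAnnotation]
    decoys: list[TranscriptAnnotation]
    read_provenance: dict[str, str]
    seed: int


@dataclass
class SimResult:
    truth: SimTruth
    reads: list[AlignedRead]
    chrom_lengths: dict[str, int]


# ---------------------------------------------------------------------------
# model placement and read sampling
# ---------------------------------------------------------------------------


def _draw_exons(
    rng: np.random.Generator,
    chrom: str,
    strand: str,
    start: int,
    n_exons: int,
    cfg: SimConfig,
) -> list[GenomicInterval]:
    exons = []
    pos = start
    for i in range(n_exons):
        elen = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        exons.append(GenomicInterval(chrom, pos, pos + elen, strand))
        pos += elen
        if i < n_exons - 1:
            pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
    return exons


def _exonic_length(exons: Sequence[GenomicInterval]) -> int:
    return sum(len(e) for e in exons)


def _sample_reads(
    rng: np.random.Generator,
    model: TranscriptAnnotation,
    cfg: SimConfig,
    id_prefix: str,
) -> list[AlignedRead]:
    """Uniform sampling of read start positions in transcript coordinates,
    mapped back to genomic blocks through the exon structure."""
    exons = model.exons
    tlen = _exonic_length(exons)
    rl = cfg.read_length
    if tlen < rl:
        return []
    n_reads = max(1, int(round(cfg.depth * tlen / rl)))
    max_start = tlen - rl
    # cumulative exonic offsets for transcript->genome projection
    offsets = np.cumsum([0] + [len(e) for e in exons])

    if cfg.spliced_read_fraction is None or len(exons) == 1:
        starts = rng.integers(0, max_start + 1, size=n_reads)
    else:
        boundary = [offsets[i] for i in range(1, len(exons))]
        crossing = sorted(
            {
                s
                for b in boundary
                for s in range(max(0, b - rl + 1), min(b, max_start) + 1)
                if s + rl > b
            }
        )
        non_crossing = sorted(set(range(0, max_start + 1)) - set(crossing))
        starts = []
        for _ in range(n_reads):
            pool = (
                crossing
                if crossing and rng.random() < cfg.spliced_read_fraction
                else non_crossing or crossing
            )
            starts.append(pool[int(rng.integers(0, len(pool)))])
        starts = np.asarray(starts)

    reads: list[AlignedRead] = []
    chrom, strand = model.interval.chrom, model.interval.strand
    for k, t_start in enumerate(sorted(int(s) for s in starts)):
        blocks: list[GenomicInterval] = []
        remaining = rl
        pos = t_start
        for i, e in enumerate(exons):
            if remaining == 0:
                break
            if pos >= offsets[i + 1]:
                continue
            within = pos - offsets[i]
            take = min(remaining, len(e) - within)
            blocks.append(
                GenomicInterval(chrom, e.start + within, e.start + within + take, strand)
            )
            remaining -= take
            pos += take
        read_id = f"{id_prefix}_{k}"
        reads.append(
            AlignedRead(
                read_id=read_id,
                interval=GenomicInterval(chrom, blocks[0].start, blocks[-1].end, strand),
                blocks=blocks,
                is_unique=True,
                mapq=50,
            )
        )
    return reads


def simulate(config: SimConfig) -> SimResult:
    """Generate genome annotation, planted NTRs, decoys and reads in memory.

    Models (genes, NTRs, decoys) are shuffled and laid out left to right per
    chromosome with inter-model gaps of at least ``min_gene_gap`` bp, so no
    planted NTR is within D1 of a gene nor within D2 of another model under
    the discovery defaults.  Raises ValueError naming the constraint when the
    genome cannot host all models.
    """
    rng = np.random.default_rng(config.seed)
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)
    }
    chroms = list(chrom_lengths)
    if not chroms and (config.n_genes or config.n_ntrs or config.decoy_singletons):
        raise ValueError("placement infeasible: no chromosomes configured")

    # plan one entry per model: (kind, index)
    plan = (
        [("gene", i) for i in range(config.n_genes)]
        + [("ntr", i) for i in range(config.n_ntrs)]
        + [("decoy", i) for i in range(config.decoy_singletons)]
    )
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    genes: list[TranscriptAnnotation] = []
    ntr_models: list[TranscriptAnnotation] = []
    decoys: list[TranscriptAnnotation] = []

    cursor = {c: 0 for c in chroms}
    for j, (kind, idx) in enumerate(plan):
        chrom = chroms[j % len(chroms)]
        strand = "+" if rng.random() < 0.5 else "-"
        gap = config.min_gene_gap + int(rng.integers(0, config.min_gene_gap // 2 + 1))
        start = cursor[chrom] + gap
        if kind == "gene":
            n_ex = int(rng.integers(config.gene_exons[0], config.gene_exons[1] + 1))
            exons = _draw_exons(rng, chrom, strand, start, n_ex, config)
            model = TranscriptAnnotation(
                transcript_id=f"gene{idx + 1}.t1",
                gene_id=f"gene{idx + 1}",
                interval=GenomicInterval(chrom, exons[0].start, exons[-1].end, strand),
                exons=exons,
            )
            genes.append(model)
        elif kind == "ntr":
            n_ex = int(rng.integers(config.ntr_exons[0], config.ntr_exons[1] + 1))
            exons = _draw_exons(rng, chrom, strand, start, n_ex, config)
            model = TranscriptAnnotation(
                transcript_id=f"truthNTR{idx + 1}",
                gene_id=f"truthNTR{idx + 1}",
                interval=GenomicInterval(chrom, exons[0].start, exons[-1].end, strand),
                exons=exons,
            )
            ntr_models.append(model)
        else:
            dlen = int(rng.integers(config.decoy_length[0], config.decoy_length[1] + 1))
            dlen = max(dlen, config.read_length)
            exons = [GenomicInterval(chrom, start, start + dlen, strand)]
            model = TranscriptAnnotation(
                transcript_id=f"decoy{idx + 1}",
                gene_id=f"decoy{idx + 1}",
                interval=exons[0],
                exons=exons,
            )
            decoys.append(model)
        if model.interval.end > chrom_lengths[chrom]:
            raise ValueError(
                "placement infeasible: chrom_length too small for the requested "
                f"models at min_gene_gap={config.min_gene_gap} "
                f"({chrom}: need > {model.interval.end} bp)"
            )
        cursor[chrom] = model.interval.end

    reads: list[AlignedRead] = []
    provenance: dict[str, str] = {}
    for model in genes + ntr_models + decoys:
        new = _sample_reads(rng, model, config, id_prefix=model.transcript_id)
        for r in new:
            provenance[r.read_id] = model.transcript_id
        reads.extend(new)

    truth = SimTruth(
        genes=sorted(genes, key=_model_key),
        ntr_models=sorted(ntr_models, key=_model_key),
        decoys=sorted(decoys, key=_model_key),
        read_provenance=provenance,
        seed=config.seed,
    )
    return SimResult(truth=truth, reads=reads, chrom_lengths=chrom_lengths)


def _model_key(t: TranscriptAnnotation):
    return (natural_chrom_key(t.interval.chrom), t.interval.start)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_sim(result: SimResult, out_prefix: str) -> dict[str, str]:
    """Write genes.gtf, reads.sam (coordinate sorted), truth.bed (BED12 of
    planted NTR models) and truth.json; byte-identical for a fixed seed."""
    paths = {
        "gtf": f"{out_prefix}.genes.gtf",
        "sam": f"{out_prefix}.reads.sam",
        "bed": f"{out_prefix}.truth.bed",
        "json": f"{out_prefix}.truth.json",
    }
    write_gtf(result.truth.genes, paths["gtf"], source="ntrscout_sim")
    _write_sam(result, paths["sam"])
    write_bed12(
        [
            Bed12Record(
                chrom=m.interval.chrom,
                start=m.interval.start,
                end=m.interval.end,
                name=m.transcript_id,
                score=max(len(m.exons) - 1, 0),
                strand=m.interval.strand,
                blocks=list(m.exons),
            )
            for m in result.truth.ntr_models
        ],
        paths["bed"],
    )
    with open(paths["json"], "w") as out:
        json.dump(
            {
                "seed": result.truth.seed,
                "chrom_lengths": result.chrom_lengths,
                "genes": [_model_json(m) for m in result.truth.genes],
                "ntr_models": [_model_json(m) for m in result.truth.ntr_models],
                "decoys": [_model_json(m) for m in result.truth.decoys],
                "read_provenance": result.truth.read_provenance,
            },
            out,
            indent=1,
            sort_keys=True,
        )
        out.write("\n")
    return paths


def _model_json(m: TranscriptAnnotation) -> dict:
    return {
        "transcript_id": m.transcript_id,
        "gene_id": m.gene_id,
        "chrom": m.interval.chrom,
        "start": m.interval.start,
        "end": m.interval.end,
        "strand": m.interval.strand,
        "exons": [[e.start, e.end] for e in m.exons],
    }


def _write_sam(result: SimResult, path: str) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": name, "LN": length}
            for name, length in result.chrom_lengths.items()
        ],
    }
    chrom_ids = {name: i for i, name in enumerate(result.chrom_lengths)}
    ordered = sorted(
        result.reads,
        key=lambda r: (chrom_ids[r.interval.chrom], r.interval.start, r.read_id),
    )
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in ordered:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = r.read_id
            rec.flag = 16 if r.interval.strand == "-" else 0
            rec.reference_id = chrom_ids[r.interval.chrom]
            rec.reference_start = r.interval.start
            rec.mapping_quality = r.mapq
            cigar: list[tuple[int, int]] = []
            for i, b in enumerate(r.blocks):
                if i:
                    cigar.append((3, b.start - r.blocks[i - 1].end))
                cigar.append((0, len(b)))
            rec.cigartuples = cigar
            rec.query_sequence = "A" * sum(len(b) for b in r.blocks)
            rec.set_tag("NH", 1)
            out.write(rec)


# ---------------------------------------------------------------------------
# evaluation against truth
# ---------------------------------------------------------------------------


@dataclass
class Evaluation:
    precision: float
    recall: float
    matched: list[tuple[str, str, float]] = field(default_factory=list)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(shared/len(a), shared/len(b)); 0 across chromosomes."""
    shared = a.overlap_len(b)
    if shared == 0:
        return 0.0
    return min(shared / len(a), shared / len(b))


def evaluate_calls(
    calls: Sequence[NTRCall],
    truth: SimTruth,
    min_reciprocal_overlap: float = 0.5,
) -> Evaluation:
    """Greedy one-to-one matching of calls to truth models by descending
    same-strand reciprocal span overlap.

    precision = matched / calls (1.0 when there are no calls: vacuously no
    false positives); recall = matched / truth models.
    """
    pairs = []
    for c in calls:
        for m in truth.ntr_models:
            if c.span.strand != m.interval.strand:
                continue
            ro = reciprocal_overlap(c.span, m.interval)
            if ro >= min_reciprocal_overlap:
                pairs.append((ro, c.ntr_id, m.transcript_id))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_calls: set[str] = set()
    used_truth: set[str] = set()
    matched: list[tuple[str, str, float]] = []
    for ro, call_id, truth_id in pairs:
        if call_id in used_calls or truth_id in used_truth:
            continue
        used_calls.add(call_id)
        used_truth.add(truth_id)
        matched.append((call_id, truth_id, ro))
    precision = len(matched) / len(calls) if calls else 1.0
    recall = len(matched) / len(truth.ntr_models) if truth.ntr_models else 1.0
    return Evaluation(precision=precision, recall=recall, matched=matched)
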