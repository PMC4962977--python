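"""Readers and writers for the standard formats the pipeline touches.

All positions are held internally as 0-based half-open intervals on a named
sequence and strand.  Conversion to the 1-based inclusive convention of GTF
and of the tabular report happens only at the format boundary; BED is already
0-based half-open so BED I/O needs no shift.
"""

from __future__ import annotations

import bisect
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import gffutils
import pysam
from intervaltree import IntervalTree

STRANDS = ("+", "-")


class FormatError(ValueError):
    """A record that cannot be interpreted under the expected format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share >= 1 bp (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class SpliceJunction:
    """An intron inferred from a gapped alignment.

    ``intron_start`` is the first intronic base (0-based), ``intron_end`` is
    one past the last intronic base; identity is the full tuple, so the same
    intron seen on opposite strands counts as two sites.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValueError("intron_start must be < intron_end")


@dataclass
class AlignedRead:
    """One uniquely mapped read as strand-tagged aligned blocks.

    ``blocks`` are the gapless aligned segments; consecutive blocks are
    separated by reference skips (introns).  ``interval`` is the hull of the
    blocks, so a spliced read spans its intron.
    """

    read_id: str
    interval: GenomicInterval
    blocks: list[GenomicInterval]
    is_unique: bool = True
    mapq: int = 255

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("read must have at least one block")
        for prev, nxt in zip(self.blocks, self.blocks[1:]):
            if nxt.start <= prev.end:
                raise ValueError("read blocks must be sorted with positive gaps")
        hull = (self.blocks[0].start, self.blocks[-1].end)
        if (self.interval.start, self.interval.end) != hull:
            raise ValueError("read interval must equal the hull of its blocks")

    @property
    def junctions(self) -> list[SpliceJunction]:
        """Introns between consecutive blocks."""
        iv = self.interval
        return [
            SpliceJunction(iv.chrom, prev.end, nxt.start, iv.strand)
            for prev, nxt in zip(self.blocks, self.blocks[1:])
        ]


@dataclass
class TranscriptAnnotation:
    """An annotated transcript with its exon structure."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError("transcript must have at least one exon")


# ---------------------------------------------------------------------------
# annotation index
# ---------------------------------------------------------------------------


class AnnotationIndex:
    """Transcripts indexed per (chrom, strand) for overlap and nearest-gap
    queries against transcript spans."""

    def __init__(self, transcripts: Iterable[TranscriptAnnotation] = ()):
        self.transcripts: list[TranscriptAnnotation] = list(transcripts)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        # sorted start coords and sorted end coords per key, for gap queries
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._ends: dict[tuple[str, str], list[int]] = {}
        for t in self.transcripts:
            key = (t.interval.chrom, t.interval.strand)
            self._trees.setdefault(key, IntervalTree()).addi(
                t.interval.start, t.interval.end, t
            )
            self._starts.setdefault(key, []).append(t.interval.start)
            self._ends.setdefault(key, []).append(t.interval.end)
        for key in self._starts:
            self._starts[key].sort()
            self._ends[key].sort()

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def n_genes(self) -> int:
        return len({t.gene_id for t in self.transcripts})

    def _keys_for(self, interval: GenomicInterval, same_strand: bool):
        if same_strand:
            return [(interval.chrom, interval.strand)]
        return [(interval.chrom, s) for s in STRANDS]

    def overlapping(
        self, interval: GenomicInterval, same_strand: bool = True
    ) -> list[TranscriptAnnotation]:
        hits: list[TranscriptAnnotation] = []
        for key in self._keys_for(interval, same_strand):
            tree = self._trees.get(key)
            if tree is not None:
                hits.extend(h.data for h in tree.overlap(interval.start, interval.end))
        return hits

    def distance(
        self, interval: GenomicInterval, same_strand: bool = True
    ) -> Optional[int]:
        """Gap in bp to the nearest qualifying transcript span.

        Returns 0 on any overlap, the minimal half-open gap
        (``next.start - prev.end``) otherwise, or None when no qualifying
        transcript exists on the chromosome.
        """
        if self.overlapping(interval, same_strand):
            return 0
        best: Optional[int] = None
        for key in self._keys_for(interval, same_strand):
            ends = self._ends.get(key)
            starts = self._starts.get(key)
            if not ends:
                continue
            # nearest transcript ending at or before our start
            i = bisect.bisect_right(ends, interval.start)
            if i > 0:
                gap = interval.start - ends[i - 1]
                best = gap if best is None else min(best, gap)
            # nearest transcript starting at or after our end
            j = bisect.bisect_left(starts, interval.end)
            if j < len(starts):
                gap = starts[j] - interval.end
                best = gap if best is None else min(best, gap)
        return best


# ---------------------------------------------------------------------------
# alignment reading
# ---------------------------------------------------------------------------

#: CIGAR ops that consume the reference within a block (M, D, =, X)
_REF_BLOCK_OPS = {0, 2, 7, 8}
_REF_SKIP = 3


@dataclass
class UniquenessPolicy:
    """Accept a read as uniquely mapped.

    If the NH tag is present it must equal 1; otherwise mapping quality must
    reach ``mapq_threshold``.  The tag check can be disabled to rely on MAPQ
    alone.
    """

    use_nh_tag: bool = True
    mapq_threshold: int = 20

    def accepts(self, rec: pysam.AlignedSegment) -> bool:
        if self.use_nh_tag and rec.has_tag("NH"):
            return rec.get_tag("NH") == 1
        return rec.mapping_quality >= self.mapq_threshold


def _blocks_from_cigar(rec: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Aligned blocks from the CIGAR: deletions stay inside a block, only
    reference skips (N) split blocks."""
    blocks: list[tuple[int, int]] = []
    pos = rec.reference_start
    block_start: Optional[int] = None
    for op, length in rec.cigartuples:
        if op in _REF_BLOCK_OPS:
            if block_start is None:
                block_start = pos
            pos += length
        elif op == _REF_SKIP:
            if block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += length
        # I, S, H, P: no reference advance
    if block_start is not None:
        blocks.append((block_start, pos))
    return blocks


def _record_strand(rec: pysam.AlignedSegment, strand_tag: Optional[str]) -> str:
    if strand_tag and rec.has_tag(strand_tag):
        value = rec.get_tag(strand_tag)
        if value in STRANDS:
            return value
    return "-" if rec.is_reverse else "+"


def read_alignments(
    path: str | os.PathLike,
    policy: Optional[UniquenessPolicy] = None,
    strand_tag: Optional[str] = None,
    skip_duplicates: bool = False,
) -> Iterator[AlignedRead]:
    """Stream uniquely mapped reads from a SAM/BAM file.

    Unmapped, secondary and supplementary records are always skipped; reads
    failing the uniqueness policy are skipped silently.  ``strand_tag`` (e.g.
    ``"XS"``) switches strand assignment from the alignment flag to a
    transcription-strand tag when the tag is present on a record.

    Raises FormatError (with the record name) on a mapped record whose CIGAR
    yields no aligned block.
    """
    if policy is None:
        policy = UniquenessPolicy()
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if skip_duplicates and rec.is_duplicate:
                continue
            if not policy.accepts(rec):
                continue
            if not rec.cigartuples:
                raise FormatError(f"mapped record without CIGAR: {rec.query_name}")
            raw = _blocks_from_cigar(rec)
            if not raw:
                raise FormatError(f"no aligned block in record {rec.query_name}")
            strand = _record_strand(rec, strand_tag)
            chrom = rec.reference_name
            blocks = [GenomicInterval(chrom, s, e, strand) for s, e in raw]
            yield AlignedRead(
                read_id=rec.query_name,
                interval=GenomicInterval(chrom, raw[0][0], raw[-1][1], strand),
                blocks=blocks,
                is_unique=True,
                mapq=rec.mapping_quality,
            )


# ---------------------------------------------------------------------------
# annotation reading / writing
# ---------------------------------------------------------------------------


def read_annotation(path: str | os.PathLike) -> AnnotationIndex:
    """Load a GTF into an :class:`AnnotationIndex`.

    Transcript spans are inferred from exon hulls when the GTF carries only
    exon features (gffutils does the inference).  GTF coordinates (1-based
    inclusive) are converted to the internal 0-based half-open convention.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0 or not _has_features(path):
        return AnnotationIndex([])
    _validate_exon_attributes(path)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, verbose=False
    )
    transcripts: list[TranscriptAnnotation] = []
    for t in db.features_of_type("transcript"):
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(t, featuretype="exon", order_by="start")
        ]
        if not exons:
            exons = [GenomicInterval(t.seqid, t.start - 1, t.end, t.strand)]
        gene_id = (t.attributes.get("gene_id") or [t.id])[0]
        transcripts.append(
            TranscriptAnnotation(
                transcript_id=t.id,
                gene_id=gene_id,
                interval=GenomicInterval(
                    t.seqid, exons[0].start, exons[-1].end, t.strand
                ),
                exons=exons,
            )
        )
    return AnnotationIndex(transcripts)


def _has_features(path: str | os.PathLike) -> bool:
    with open(path) as fh:
        return any(line.strip() and not line.startswith("#") for line in fh)


def _validate_exon_attributes(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if cols[2] == "exon" and "transcript_id" not in cols[8]:
                raise FormatError(
                    f"{path}:{lineno}: exon feature without transcript_id"
                )


def write_gtf(transcripts: Sequence[TranscriptAnnotation], path: str | os.PathLike,
              source: str = "ntrscout") -> None:
    """Write transcript + exon features, converting back to 1-based inclusive."""
    with open(path, "w") as out:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            iv = t.interval
            out.write(
                f"{iv.chrom}\t{source}\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )
            for e in t.exons:
                out.write(
                    f"{e.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


@dataclass
class Bed12Record:
    """A blocked BED12 line (0-based half-open, per the BED standard)."""

    chrom: str
    start: int
    end: int
    name: str
    score: int
    strand: str
    blocks: list[GenomicInterval] = field(default_factory=list)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


def write_bed12(records: Iterable[Bed12Record], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for r in records:
            if not r.blocks:
                raise ValueError(f"BED12 record {r.name} has no blocks")
            sizes = ",".join(str(len(b)) for b in r.blocks)
            starts = ",".join(str(b.start - r.start) for b in r.blocks)
            out.write(
                "\t".join(
                    [
                        r.chrom,
                        str(r.start),
                        str(r.end),
                        r.name,
                        str(min(r.score, 1000)),
                        r.strand,
                        str(r.start),
                        str(r.end),
                        "0",
                        str(len(r.blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path: str | os.PathLike) -> list[Bed12Record]:
    records: list[Bed12Record] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            strand = cols[5]
            sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
            offs = [int(x) for x in cols[11].rstrip(",").split(",")]
            blocks = [
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offs, sizes)
            ]
            records.append(
                Bed12Record(chrom, start, end, cols[3], int(cols[4]), strand, blocks)
            )
    return records


def write_junction_bed(
    junction_support: dict[SpliceJunction, int], path: str | os.PathLike
) -> None:
    """BED6 of splice junctions: name is donor-acceptor, score the read support."""
    with open(path, "w") as out:
        for j in sorted(junction_support):
            out.write(
                f"{j.chrom}\t{j.intron_start}\t{j.intron_end}\t"
                f"{j.intron_start}-{j.intron_end}\t"
                f"{min(junction_support[j], 1000)}\t{j.strand}\n"
            )


# ---------------------------------------------------------------------------
# ordering helpers
# ---------------------------------------------------------------------------

_NAT_SPLIT = re.compile(r"(\d+)")


def natural_chrom_key(name: str) -> tuple:
    """Natural sort key: chr2 before chr10."""
    return tuple(
        int(tok) if tok.isdigit() else tok
        for tok in _NAT_SPLIT.split(name)
        if tok != ""
    )


def sort_reads(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Sort reads by (chrom, strand, start, end) using natural chromosome order."""
    return sorted(
        reads,
        key=lambda r: (
            natural_chrom_key(r.interval.chrom),
            r.interval.strand,
            r.interval.start,
            r.interval.end,
            r.read_id,
        ),
    )
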