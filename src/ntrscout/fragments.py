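"""Fragment construction from uniquely mapped reads.

A fragment is a maximal group of same-strand reads whose spans overlap by at
least one base pair, linked transitively; a spliced read on its own is also a
fragment, its intron lying inside the fragment span.  Bookended reads (zero
shared bases) never merge.  Fragments are the atomic transcribed units the
downstream clustering operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .io_formats import (
    AlignedRead,
    GenomicInterval,
    SpliceJunction,
    sort_reads,
)


@dataclass
class Fragment:
    """A maximal overlap-connected group of same-strand reads.

    ``interval`` spans from the lowest read start to the highest read end
    (introns of spliced reads included); ``coverage_blocks`` is the merged
    union of the member reads' aligned blocks; ``junction_support`` maps each
    distinct splice-junction site to its supporting read count.
    """

    interval: GenomicInterval
    read_count: int
    coverage_blocks: list[GenomicInterval]
    junction_support: dict[SpliceJunction, int] = field(default_factory=dict)

    @property
    def junctions(self) -> set[SpliceJunction]:
        return set(self.junction_support)

    @property
    def junction_count(self) -> int:
        return len(self.junction_support)

    def __len__(self) -> int:
        return len(self.interval)


def merge_coverage(blocks: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted set of disjoint intervals covering the input union.

    Coverage semantics: bookended blocks DO merge here (they describe
    transcribed bases, not read connectivity).  All blocks must share one
    (chrom, strand).
    """
    blocks = sorted(blocks, key=lambda b: (b.start, b.end))
    if not blocks:
        return []
    merged: list[list[int]] = [[blocks[0].start, blocks[0].end]]
    chrom, strand = blocks[0].chrom, blocks[0].strand
    for b in blocks[1:]:
        if b.chrom != chrom or b.strand != strand:
            raise ValueError("merge_coverage requires one (chrom, strand)")
        if b.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b.end)
        else:
            merged.append([b.start, b.end])
    return [GenomicInterval(chrom, s, e, strand) for s, e in merged]


def build_fragments(
    reads: Iterable[AlignedRead],
) -> dict[tuple[str, str], list[Fragment]]:
    """Group reads into fragments, per (chrom, strand), sorted by start.

    Two reads join one fragment iff their spans share >= 1 bp on the same
    strand (transitively); connectivity uses the read span, so a spliced
    read bridges across its intron.  Output fragments on one strand never
    share a base (bookended fragments are allowed).
    """
    out: dict[tuple[str, str], list[Fragment]] = {}
    current: list[AlignedRead] = []

    def flush() -> None:
        if not current:
            return
        iv = current[0].interval
        span = GenomicInterval(
            iv.chrom,
            min(r.interval.start for r in current),
            max(r.interval.end for r in current),
            iv.strand,
        )
        support: dict[SpliceJunction, int] = {}
        blocks: list[GenomicInterval] = []
        for r in current:
            blocks.extend(r.blocks)
            for j in r.junctions:
                support[j] = support.get(j, 0) + 1
        frag = Fragment(
            interval=span,
            read_count=len(current),
            coverage_blocks=merge_coverage(blocks),
            junction_support=support,
        )
        out.setdefault((span.chrom, span.strand), []).append(frag)
        current.clear()

    for read in sort_reads(reads):
        iv = read.interval
        if current:
            cur = current[0].interval
            cur_end = max(r.interval.end for r in current)
            same_group = (
                iv.chrom == cur.chrom
                and iv.strand == cur.strand
                and iv.start < cur_end  # >= 1 bp shared; bookended stays apart
            )
            if not same_group:
                flush()
        current.append(read)
    flush()
    return out


def all_fragments(per_strand: dict[tuple[str, str], list[Fragment]]) -> list[Fragment]:
    """Flatten a per-(chrom, strand) fragment map in genomic order."""
    from .io_formats import natural_chrom_key

    keys = sorted(per_strand, key=lambda k: (natural_chrom_key(k[0]), k[1]))
    flat: list[Fragment] = []
    for k in keys:
        flat.extend(per_strand[k])
    return flat


def expand_to_reads(fragment: Fragment) -> AlignedRead:
    """A single synthetic read covering the fragment span with the fragment's
    block structure; used to re-fragment fragments (stability checks)."""
    return AlignedRead(
        read_id=f"frag:{fragment.interval.chrom}:{fragment.interval.start}",
        interval=fragment.interval,
        blocks=list(fragment.coverage_blocks),
    )
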