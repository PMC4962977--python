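import random

import pysam
import pytest

from ntrscout import AlignedRead, GenomicInterval


def make_read(chrom, start, end, strand="+", read_id=None, blocks=None):
    """Build an AlignedRead from a span or explicit (start, end) blocks."""
    if blocks is None:
        blocks = [(start, end)]
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in blocks]
    return AlignedRead(
        read_id=read_id or f"r{chrom}:{start}-{end}{strand}",
        interval=GenomicInterval(chrom, ivs[0].start, ivs[-1].end, strand),
        blocks=ivs,
        mapq=50,
    )


def random_reads(rng: random.Random, n, chrom="chr1", span=10_000, read_len=50,
                 strands=("+", "-")):
    """Unspliced reads with random starts and strands, unique ids."""
    reads = []
    for i in range(n):
        start = rng.randrange(0, span - read_len)
        strand = rng.choice(strands)
        reads.append(make_read(chrom, start, start + read_len, strand,
                               read_id=f"rr{i}"))
    return reads


def write_sam(path, reads, chrom_lengths):
    """Write AlignedReads to a coordinate-sorted SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    ids = {c: i for i, c in enumerate(chrom_lengths)}
    ordered = sorted(reads, key=lambda r: (ids[r.interval.chrom],
                                           r.interval.start, r.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in ordered:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = r.read_id
            rec.flag = 16 if r.interval.strand == "-" else 0
            rec.reference_id = ids[r.interval.chrom]
            rec.reference_start = r.interval.start
            rec.mapping_quality = r.mapq
            cigar = []
            for i, b in enumerate(r.blocks):
                if i:
                    cigar.append((3, b.start - r.blocks[i - 1].end))
                cigar.append((0, len(b)))
            rec.cigartuples = cigar
            rec.query_sequence = "A" * sum(len(b) for b in r.blocks)
            rec.set_tag("NH", 1)
            out.write(rec)
    return path


@pytest.fixture
def rng():
    return random.Random(20160727)
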