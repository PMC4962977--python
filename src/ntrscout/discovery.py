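"""The NTR discovery workflow.

Fragments built from uniquely mapped reads are screened against the primary
annotation: fragments overlapping an annotated transcript on the same strand,
or lying within D1 bp of one, are excluded (they may be unannotated parts of
known genes).  Surviving fragments are chained into clusters wherever the gap
between consecutive same-strand fragments is within D2.  A cluster becomes a
putative NTR when it carries at least ``min_junctions`` distinct splice
junction sites and does not overlap any transcript of the secondary
annotations; junctionless one-fragment clusters longer than the singleton
threshold are reported separately and never called.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .fragments import Fragment, all_fragments, build_fragments, merge_coverage
from .io_formats import (
    AlignedRead,
    AnnotationIndex,
    Bed12Record,
    GenomicInterval,
    SpliceJunction,
    natural_chrom_key,
    read_alignments,
    read_annotation,
    write_bed12,
)


@dataclass
class DiscoveryParams:
    """Tunable distances and filters of the discovery workflow.

    D1: exclusion distance (bp) to any annotated transcript; a fragment at
    most D1 away (or overlapping) is discarded.  D2: linkage distance (bp);
    consecutive same-strand fragments with a gap <= D2 join one cluster (set
    ``d2_strict`` for a strict < D2 rule).  ``min_junctions`` distinct splice
    sites are required to call a cluster; junctionless single-fragment
    clusters longer than ``singleton_min_len`` are binned as singletons.
    """

    d1: int = 1000
    d2: int = 5000
    min_junctions: int = 2
    singleton_min_len: int = 50
    same_strand_only: bool = True
    d2_strict: bool = False

    def __post_init__(self) -> None:
        if min(self.d1, self.d2, self.min_junctions, self.singleton_min_len) < 0:
            raise ValueError("discovery parameters must be non-negative")

    def linked(self, gap: int) -> bool:
        return gap < self.d2 if self.d2_strict else gap <= self.d2


@dataclass
class Cluster:
    """A chain of same-strand fragments with consecutive gaps within D2."""

    fragments: list[Fragment]
    status: str = "candidate"

    @property
    def interval(self) -> GenomicInterval:
        first = self.fragments[0].interval
        return GenomicInterval(
            first.chrom,
            min(f.interval.start for f in self.fragments),
            max(f.interval.end for f in self.fragments),
            first.strand,
        )

    @property
    def junction_support(self) -> dict[SpliceJunction, int]:
        support: dict[SpliceJunction, int] = {}
        for f in self.fragments:
            for j, n in f.junction_support.items():
                support[j] = support.get(j, 0) + n
        return support

    @property
    def junction_count(self) -> int:
        """Distinct splice junction sites across member fragments."""
        return len({j for f in self.fragments for j in f.junction_support})

    @property
    def read_count(self) -> int:
        return sum(f.read_count for f in self.fragments)

    @property
    def coverage_blocks(self) -> list[GenomicInterval]:
        return merge_coverage(
            [b for f in self.fragments for b in f.coverage_blocks]
        )


@dataclass
class NTRCall:
    """A called novel transcribed region.

    The reported span is the hull of read coverage; ``exonic_length`` is the
    total merged covered length, the length term used for FPKM.
    """

    ntr_id: str
    cluster: Cluster
    span: GenomicInterval
    exonic_length: int
    read_count: int

    @property
    def junction_count(self) -> int:
        return self.cluster.junction_count

    def to_bed12(self) -> Bed12Record:
        blocks = self.cluster.coverage_blocks
        if not blocks:
            raise ValueError(f"call {self.ntr_id} has no coverage blocks")
        return Bed12Record(
            chrom=self.span.chrom,
            start=self.span.start,
            end=self.span.end,
            name=self.ntr_id,
            score=min(self.junction_count, 1000),
            strand=self.span.strand,
            blocks=blocks,
        )


@dataclass
class DiscoveryReport:
    """Count ledger of one discovery run.

    Invariant: ``n_fragments_total`` equals the sum of the in-annotation,
    proximal and clustered fragment bins.
    """

    n_fragments_total: int = 0
    n_fragments_in_annotation: int = 0
    n_fragments_proximal_D1: int = 0
    n_fragments_clustered: int = 0
    n_clusters: int = 0
    n_clusters_junction_filtered: int = 0
    n_singletons: int = 0
    n_removed_secondary: int = 0
    n_ntr_final: int = 0

    def check(self) -> None:
        if self.n_fragments_total != (
            self.n_fragments_in_annotation
            + self.n_fragments_proximal_D1
            + self.n_fragments_clustered
        ):
            raise AssertionError("fragment ledger does not balance")
        if self.n_ntr_final > self.n_clusters:
            raise AssertionError("more calls than clusters")

    def as_dict(self) -> dict[str, int]:
        return dict(vars(self))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def distance_to_annotation(
    fragment: Fragment, index: AnnotationIndex, same_strand: bool = True
) -> Optional[int]:
    """Gap (bp) from the fragment span to the nearest qualifying transcript;
    0 on overlap, None when no qualifying transcript shares the chromosome."""
    return index.distance(fragment.interval, same_strand=same_strand)


def filter_fragments(
    fragments: Sequence[Fragment],
    index: AnnotationIndex,
    params: DiscoveryParams,
) -> tuple[list[Fragment], list[Fragment], list[Fragment]]:
    """Partition fragments into (kept, in-annotation, proximal-within-D1).

    A fragment overlapping an annotated transcript (distance 0) is binned as
    in-annotation; one at most D1 bp away is proximal; the rest are kept for
    clustering.  The D1 boundary is inclusive: a gap of exactly D1 is
    excluded.
    """
    kept: list[Fragment] = []
    in_annotation: list[Fragment] = []
    proximal: list[Fragment] = []
    for f in fragments:
        d = distance_to_annotation(f, index, same_strand=params.same_strand_only)
        if d == 0:
            in_annotation.append(f)
        elif d is not None and d <= params.d1:
            proximal.append(f)
        else:
            kept.append(f)
    return kept, in_annotation, proximal


def cluster_fragments(
    kept: Sequence[Fragment], params: DiscoveryParams
) -> list[Cluster]:
    """Chain same-strand fragments into clusters under the D2 gap rule.

    Clusters are the connected components of the "gap within D2" relation on
    consecutive fragments; a single sweep over position-sorted fragments per
    (chrom, strand) computes them.
    """
    by_key: dict[tuple[str, str], list[Fragment]] = {}
    for f in kept:
        by_key.setdefault((f.interval.chrom, f.interval.strand), []).append(f)

    clusters: list[Cluster] = []
    for key in sorted(by_key, key=lambda k: (natural_chrom_key(k[0]), k[1])):
        frags = sorted(by_key[key], key=lambda f: (f.interval.start, f.interval.end))
        chain: list[Fragment] = []
        chain_end = 0
        for f in frags:
            if chain and not params.linked(max(0, f.interval.start - chain_end)):
                clusters.append(Cluster(fragments=chain))
                chain = []
            chain.append(f)
            chain_end = max(chain_end, f.interval.end) if len(chain) > 1 else f.interval.end
        if chain:
            clusters.append(Cluster(fragments=chain))
    return clusters


def filter_clusters(
    clusters: Sequence[Cluster], params: DiscoveryParams
) -> tuple[list[Cluster], list[Cluster], list[Cluster]]:
    """Split clusters into (candidates, rejected_few_junctions, singletons).

    Candidates carry >= ``min_junctions`` distinct junction sites.  Among the
    rest, junctionless one-fragment clusters longer than
    ``singleton_min_len`` are singletons (reported, never called); everything
    else is rejected for lack of junction support.
    """
    candidates: list[Cluster] = []
    rejected: list[Cluster] = []
    singletons: list[Cluster] = []
    for c in clusters:
        if c.junction_count >= params.min_junctions:
            c.status = "candidate"
            candidates.append(c)
        elif (
            len(c.fragments) == 1
            and c.junction_count == 0
            and len(c.interval) > params.singleton_min_len
        ):
            c.status = "singleton"
            singletons.append(c)
        else:
            c.status = "rejected_few_junctions"
            rejected.append(c)
    return candidates, rejected, singletons


def subtract_known(
    candidates: Sequence[Cluster],
    secondary_index: AnnotationIndex,
    params: DiscoveryParams,
) -> tuple[list[NTRCall], list[Cluster]]:
    """Drop candidates overlapping a same-strand secondary transcript by
    >= 1 bp; survivors become calls with ids assigned in genomic order."""
    removed: list[Cluster] = []
    surviving: list[Cluster] = []
    for c in candidates:
        if secondary_index.overlapping(c.interval, same_strand=True):
            c.status = "annotated_secondary"
            removed.append(c)
        else:
            surviving.append(c)
    surviving.sort(
        key=lambda c: (natural_chrom_key(c.interval.chrom), c.interval.start)
    )
    calls = []
    for i, c in enumerate(surviving, 1):
        c.status = "ntr"
        calls.append(
            NTRCall(
                ntr_id=f"NTR{i}",
                cluster=c,
                span=c.interval,
                exonic_length=sum(len(b) for b in c.coverage_blocks),
                read_count=c.read_count,
            )
        )
    return calls, removed


@dataclass
class DiscoveryResult:
    calls: list[NTRCall]
    report: DiscoveryReport
    singletons: list[Cluster] = field(default_factory=list)
    rejected: list[Cluster] = field(default_factory=list)


def run_discovery(
    alignments: Iterable[AlignedRead] | str | os.PathLike | Sequence[str | os.PathLike],
    primary: AnnotationIndex | str | os.PathLike,
    secondary: AnnotationIndex | Sequence[str | os.PathLike] | None = None,
    params: Optional[DiscoveryParams] = None,
) -> DiscoveryResult:
    """Run the full workflow: fragments -> D1 filter -> D2 clustering ->
    junction/singleton filter -> secondary subtraction.

    ``alignments`` may be AlignedRead objects, one SAM/BAM path, or several
    paths (pooled, as when combining runs and stages).  ``primary`` and the
    optional ``secondary`` annotations may be indexes or GTF paths.
    """
    params = params or DiscoveryParams()
    reads = _as_reads(alignments)
    primary_index = _as_index(primary)
    secondary_index = _merge_indexes(secondary)

    fragments = all_fragments(build_fragments(reads))
    kept, in_annot, proximal = filter_fragments(fragments, primary_index, params)
    clusters = cluster_fragments(kept, params)
    candidates, rejected, singletons = filter_clusters(clusters, params)
    calls, removed_secondary = subtract_known(candidates, secondary_index, params)

    report = DiscoveryReport(
        n_fragments_total=len(fragments),
        n_fragments_in_annotation=len(in_annot),
        n_fragments_proximal_D1=len(proximal),
        n_fragments_clustered=len(kept),
        n_clusters=len(clusters),
        n_clusters_junction_filtered=len(rejected),
        n_singletons=len(singletons),
        n_removed_secondary=len(removed_secondary),
        n_ntr_final=len(calls),
    )
    report.check()
    return DiscoveryResult(
        calls=calls, report=report, singletons=singletons, rejected=rejected
    )


def write_call_outputs(result: DiscoveryResult, out_prefix: str) -> dict[str, str]:
    """Write the BED12 calls, the report ledger and the per-call table
    (1-based inclusive coordinates, as printed reports conventionally are)."""
    import pandas as pd

    paths = {
        "bed": f"{out_prefix}.ntr.bed",
        "report": f"{out_prefix}.report.tsv",
        "table": f"{out_prefix}.table.tsv",
    }
    write_bed12([c.to_bed12() for c in result.calls], paths["bed"])
    pd.DataFrame([result.report.as_dict()]).T.reset_index().rename(
        columns={"index": "count", 0: "value"}
    ).to_csv(paths["report"], sep="\t", index=False, header=["count", "value"])
    rows = [
        {
            "ID": c.ntr_id,
            "Chr": c.span.chrom,
            "Start": c.span.start + 1,
            "End": c.span.end,
            "Read": c.read_count,
            "Fragment": len(c.cluster.fragments),
            "Strand": c.span.strand,
            "Junctions": c.junction_count,
        }
        for c in result.calls
    ]
    pd.DataFrame(
        rows,
        columns=["ID", "Chr", "Start", "End", "Read", "Fragment", "Strand", "Junctions"],
    ).to_csv(paths["table"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# input coercion
# ---------------------------------------------------------------------------


def _as_reads(alignments) -> list[AlignedRead]:
    if isinstance(alignments, (str, os.PathLike)):
        return list(read_alignments(alignments))
    alignments = list(alignments)
    if alignments and isinstance(alignments[0], (str, os.PathLike)):
        reads: list[AlignedRead] = []
        for p in alignments:
            reads.extend(read_alignments(p))
        return reads
    return alignments


def _as_index(ann) -> AnnotationIndex:
    if isinstance(ann, AnnotationIndex):
        return ann
    return read_annotation(ann)


def _merge_indexes(secondary) -> AnnotationIndex:
    if secondary is None:
        return AnnotationIndex([])
    if isinstance(secondary, AnnotationIndex):
        return secondary
    if isinstance(secondary, (str, os.PathLike)):
        return read_annotation(secondary)
    transcripts = []
    for item in secondary:
        transcripts.extend(_as_index(item).transcripts)
    return AnnotationIndex(transcripts)
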