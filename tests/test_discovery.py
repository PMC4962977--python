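"""The discovery workflow: D1 exclusion, D2 clustering, filters, calls."""

import random

import pytest

from ntrscout import (
    AnnotationIndex,
    DiscoveryParams,
    GenomicInterval,
    SpliceJunction,
    TranscriptAnnotation,
    cluster_fragments,
    distance_to_annotation,
    evaluate_calls,
    filter_clusters,
    filter_fragments,
    run_discovery,
    simulate,
    subtract_known,
)
from ntrscout.fragments import Fragment
from ntrscout.simulate import SimConfig


def frag(start, end, strand="+", chrom="chr1", junctions=(), reads=1):
    support = {
        SpliceJunction(chrom, s, e, strand): 1 for s, e in junctions
    }
    return Fragment(
        interval=GenomicInterval(chrom, start, end, strand),
        read_count=reads,
        coverage_blocks=[GenomicInterval(chrom, start, end, strand)],
        junction_support=support,
    )


def transcript(start, end, strand="+", chrom="chr1", tid="t"):
    return TranscriptAnnotation(
        transcript_id=f"{tid}:{start}", gene_id=f"g:{start}",
        interval=GenomicInterval(chrom, start, end, strand),
        exons=[GenomicInterval(chrom, start, end, strand)],
    )


# ---------------------------------------------------------------------------
# distance to annotation
# ---------------------------------------------------------------------------


def test_distance_is_half_open_gap():
    index = AnnotationIndex([transcript(0, 1000)])
    assert distance_to_annotation(frag(2000, 2500), index) == 1000


def test_distance_zero_on_overlap():
    index = AnnotationIndex([transcript(0, 1000)])
    assert distance_to_annotation(frag(900, 1200), index) == 0


def test_distance_strand_restricted():
    index = AnnotationIndex([transcript(0, 1000, strand="-")])
    assert distance_to_annotation(frag(2000, 2500), index, same_strand=True) is None
    assert distance_to_annotation(frag(2000, 2500), index, same_strand=False) == 1000


def test_distance_takes_nearest_side():
    index = AnnotationIndex([transcript(0, 1000), transcript(9000, 9500)])
    assert distance_to_annotation(frag(2000, 2500), index) == 1000
    assert distance_to_annotation(frag(8000, 8900), index) == 100


# ---------------------------------------------------------------------------
# D1 fragment filter
# ---------------------------------------------------------------------------


def test_d1_boundary_is_inclusive():
    """A gap of exactly D1 is excluded ('1 kb or less away'); D1+1 is kept."""
    index = AnnotationIndex([transcript(0, 1000)])
    params = DiscoveryParams(d1=1000)
    at_d1, beyond = frag(2000, 2500), frag(2001, 2500)
    kept, in_annot, proximal = filter_fragments([at_d1, beyond], index, params)
    assert proximal == [at_d1]
    assert kept == [beyond]
    assert in_annot == []


def test_empty_annotation_keeps_everything():
    kept, in_annot, proximal = filter_fragments(
        [frag(0, 100), frag(5000, 5100)], AnnotationIndex([]), DiscoveryParams())
    assert len(kept) == 2 and not in_annot and not proximal


def test_filter_partitions_the_input(rng):
    index = AnnotationIndex(
        [transcript(s, s + 2000, strand=st)
         for s in range(0, 50_000, 9000) for st in "+-"]
    )
    frags = []
    for _ in range(100):
        start = rng.randrange(0, 60_000)
        frags.append(frag(start, start + 300, strand=rng.choice("+-")))
    kept, in_annot, proximal = filter_fragments(frags, index, DiscoveryParams())
    assert len(kept) + len(in_annot) + len(proximal) == len(frags)
    assert set(map(id, kept)) | set(map(id, in_annot)) | set(map(id, proximal)) \
        == set(map(id, frags))


def test_antisense_overlap_keeps_fragment_by_default():
    index = AnnotationIndex([transcript(0, 1000, strand="-")])
    kept, in_annot, _ = filter_fragments([frag(500, 800, "+")], index,
                                         DiscoveryParams())
    assert len(kept) == 1 and not in_annot
    # strand-agnostic switch excludes it
    kept, in_annot, _ = filter_fragments(
        [frag(500, 800, "+")], index, DiscoveryParams(same_strand_only=False))
    assert not kept and len(in_annot) == 1


# ---------------------------------------------------------------------------
# D2 clustering
# ---------------------------------------------------------------------------


def test_cluster_gap_rule_hand_example():
    frags = [frag(0, 100), frag(3000, 3100), frag(9000, 9100)]
    clusters = cluster_fragments(frags, DiscoveryParams(d2=5000))
    assert [len(c.fragments) for c in clusters] == [2, 1]
    assert (clusters[0].interval.start, clusters[0].interval.end) == (0, 3100)


def test_single_fragment_forms_one_cluster():
    (c,) = cluster_fragments([frag(0, 100)], DiscoveryParams())
    assert len(c.fragments) == 1


def test_d2_boundary_default_inclusive_with_strict_switch():
    frags = [frag(0, 100), frag(5100, 5200)]  # gap exactly 5000
    assert len(cluster_fragments(frags, DiscoveryParams(d2=5000))) == 1
    assert len(cluster_fragments(
        frags, DiscoveryParams(d2=5000, d2_strict=True))) == 2


def brute_force_clusters(frags, params):
    """Transitive closure of pairwise same-strand linkage at gap <= D2."""
    n = len(frags)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i):
            a, b = frags[i].interval, frags[j].interval
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            gap = max(b.start - a.end, a.start - b.end, 0)
            if params.linked(gap):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(frags[i])
    return {
        (g[0].interval.chrom, g[0].interval.strand,
         min(f.interval.start for f in g), max(f.interval.end for f in g),
         len(g))
        for g in groups.values()
    }


def test_clustering_matches_brute_force_oracle(rng):
    for _ in range(20):
        frags = []
        for k in range(rng.randrange(0, 60)):
            start = rng.randrange(0, 100_000)
            frags.append(frag(start, start + rng.randrange(50, 2000),
                              strand=rng.choice("+-")))
        # fragments on one strand must be disjoint: thin them
        frags = _make_disjoint(frags)
        params = DiscoveryParams(d2=rng.choice([1000, 5000, 10_000]))
        got = {
            (c.interval.chrom, c.interval.strand, c.interval.start,
             c.interval.end, len(c.fragments))
            for c in cluster_fragments(frags, params)
        }
        assert got == brute_force_clusters(frags, params)


def _make_disjoint(frags):
    out = {}
    for f in frags:
        key = (f.interval.chrom, f.interval.strand)
        out.setdefault(key, [])
        if all(not f.interval.overlaps(g.interval) for g in out[key]):
            out[key].append(f)
    return [f for fs in out.values() for f in fs]


def test_d2_monotonicity_on_random_fixtures(rng):
    for _ in range(10):
        raw = []
        for _ in range(80):
            start = rng.randrange(0, 200_000)
            raw.append(frag(start, start + rng.randrange(100, 3000),
                            strand=rng.choice("+-")))
        frags = _make_disjoint(raw)
        n5 = len(cluster_fragments(frags, DiscoveryParams(d2=5000)))
        n10 = len(cluster_fragments(frags, DiscoveryParams(d2=10_000)))
        assert n10 <= n5


# ---------------------------------------------------------------------------
# cluster filters
# ---------------------------------------------------------------------------


def test_junction_filter_requires_two_distinct_sites():
    one = cluster_fragments([frag(0, 100, junctions=[(20, 50)])],
                            DiscoveryParams())
    two = cluster_fragments([frag(0, 200, junctions=[(20, 50), (80, 150)])],
                            DiscoveryParams())
    c1, r1, s1 = filter_clusters(one, DiscoveryParams())
    c2, r2, s2 = filter_clusters(two, DiscoveryParams())
    assert not c1 and r1
    assert c2 and not r2


def test_singleton_rule_length_over_50():
    sixty = cluster_fragments([frag(0, 60)], DiscoveryParams())
    forty = cluster_fragments([frag(0, 40)], DiscoveryParams())
    _, rejected, singles = filter_clusters(sixty + forty, DiscoveryParams())
    assert [(c.interval.start, c.interval.end) for c in singles] == [(0, 60)]
    assert [(c.interval.start, c.interval.end) for c in rejected] == [(0, 40)]


def test_exactly_50bp_junctionless_cluster_is_not_a_singleton():
    exact = cluster_fragments([frag(0, 50)], DiscoveryParams())
    _, rejected, singles = filter_clusters(exact, DiscoveryParams())
    assert not singles and len(rejected) == 1


# ---------------------------------------------------------------------------
# secondary subtraction
# ---------------------------------------------------------------------------


def _candidates(*frags):
    clusters = cluster_fragments(list(frags), DiscoveryParams())
    cands, _, _ = filter_clusters(clusters, DiscoveryParams())
    return cands


def test_empty_secondary_annotation_keeps_all_candidates():
    cands = _candidates(frag(0, 300, junctions=[(50, 100), (150, 250)]))
    calls, removed = subtract_known(cands, AnnotationIndex([]), DiscoveryParams())
    assert len(calls) == 1 and not removed
    assert calls[0].ntr_id == "NTR1"


def test_candidate_inside_secondary_transcript_removed():
    cands = _candidates(frag(100, 400, junctions=[(150, 200), (250, 350)]))
    secondary = AnnotationIndex([transcript(0, 1000)])
    calls, removed = subtract_known(cands, secondary, DiscoveryParams())
    assert not calls and len(removed) == 1


def test_antisense_secondary_overlap_keeps_candidate():
    cands = _candidates(frag(100, 400, "+", junctions=[(150, 200), (250, 350)]))
    secondary = AnnotationIndex([transcript(0, 1000, strand="-")])
    calls, removed = subtract_known(cands, secondary, DiscoveryParams())
    assert len(calls) == 1 and not removed


def test_call_ids_follow_genomic_order():
    cands = _candidates(
        frag(5000, 5400, chrom="chr10", junctions=[(5100, 5150), (5200, 5300)]),
        frag(100, 400, chrom="chr2", junctions=[(150, 200), (250, 350)]),
    )
    calls, _ = subtract_known(cands, AnnotationIndex([]), DiscoveryParams())
    assert [(c.ntr_id, c.span.chrom) for c in calls] == [
        ("NTR1", "chr2"), ("NTR2", "chr10")]


# ---------------------------------------------------------------------------
# full workflow
# ---------------------------------------------------------------------------


def test_empty_input_gives_zero_everything():
    result = run_discovery([], AnnotationIndex([]), None, DiscoveryParams())
    assert result.calls == []
    assert all(v == 0 for v in result.report.as_dict().values())


def test_simulated_run_recovers_planted_ntrs():
    sim = simulate(SimConfig(seed=1))
    index = AnnotationIndex(sim.truth.genes)
    result = run_discovery(sim.reads, index, None, DiscoveryParams())
    result.report.check()
    ev = evaluate_calls(result.calls, sim.truth, 0.5)
    assert ev.recall >= 0.9
    # calls never touch annotated genes on the same strand
    for call in result.calls:
        assert not index.overlapping(call.span, same_strand=True)
        assert call.junction_count >= 2
        d = index.distance(call.span)
        assert d is None or d > DiscoveryParams().d1


def test_report_ledger_balances_on_simulated_runs():
    for seed in (2, 3):
        sim = simulate(SimConfig(seed=seed))
        result = run_discovery(sim.reads, AnnotationIndex(sim.truth.genes))
        rep = result.report
        assert rep.n_fragments_total == (
            rep.n_fragments_in_annotation + rep.n_fragments_proximal_D1
            + rep.n_fragments_clustered)
        assert rep.n_ntr_final <= rep.n_clusters


def test_larger_d2_never_increases_cluster_count_end_to_end():
    sim = simulate(SimConfig(seed=4))
    index = AnnotationIndex(sim.truth.genes)
    n5 = run_discovery(sim.reads, index, None,
                       DiscoveryParams(d2=5000)).report.n_clusters
    n10 = run_discovery(sim.reads, index, None,
                        DiscoveryParams(d2=10_000)).report.n_clusters
    assert n10 <= n5


def test_larger_d1_never_increases_kept_fragments():
    sim = simulate(SimConfig(seed=5))
    index = AnnotationIndex(sim.truth.genes)
    kept_counts = [
        run_discovery(sim.reads, index, None,
                      DiscoveryParams(d1=d1)).report.n_fragments_clustered
        for d1 in (0, 500, 1000, 2000)
    ]
    assert kept_counts == sorted(kept_counts, reverse=True)
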