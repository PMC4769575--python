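import numpy as np
import pytest

from tntscan.align import build_kmer_index
from tntscan.assemble import ContigNode, NodeAnchor
from tntscan.classify import HybridRead
from tntscan.locus import (
    EvidenceCluster,
    EvidenceHit,
    InsertionLocus,
    PlacedPair,
    SupportCounts,
    assign_confidence,
    attach_nodes,
    cluster_evidence,
    count_spanning_pairs,
    estimate_zygosity,
    map_evidence,
    number_loci,
)


def _hit(eid, bp, kind="hybrid_LE", chrom="chr1", side=""):
    return EvidenceHit(
        evidence_id=eid, evidence_kind=kind, chrom=chrom, breakpoint=bp,
        strand="+", mapped_start=max(0, bp - 50), mapped_end=bp + 50,
        identity=1.0, element_side=side,
    )


class TestClustering:
    def test_three_close_hits_one_cluster_median_position(self):
        hits = [_hit("a", 1000), _hit("b", 1004), _hit("c", 1010)]
        clusters = cluster_evidence(hits, window=100)
        assert len(clusters) == 1
        assert clusters[0].position == 1004

    def test_distant_hits_split(self):
        clusters = cluster_evidence([_hit("a", 1000), _hit("b", 5000)], window=100)
        assert len(clusters) == 2

    def test_le_and_re_evidence_merge_into_one_locus(self):
        hits = [_hit("a", 1000, "hybrid_LE"), _hit("b", 1005, "hybrid_RE")]
        clusters = cluster_evidence(hits, window=100)
        assert len(clusters) == 1
        kinds = {m.evidence_kind for m in clusters[0].members}
        assert kinds == {"hybrid_LE", "hybrid_RE"}

    def test_chromosomes_never_mix(self):
        clusters = cluster_evidence(
            [_hit("a", 1000, chrom="chr1"), _hit("b", 1000, chrom="chr2")], window=100
        )
        assert len(clusters) == 2

    def test_even_count_takes_lower_median(self):
        clusters = cluster_evidence([_hit("a", 1000), _hit("b", 1002)], window=100)
        assert clusters[0].position == 1000


class TestAttachNodes:
    def test_node_attaches_to_cluster_on_its_element_side(self):
        clusters = cluster_evidence([_hit("a", 5000), _hit("b", 5002)], window=100)
        node = _hit("n1", 4600, kind="node", side="right")  # element to the right
        merged = attach_nodes(clusters, [node], max_dist=700, window=100)
        assert len(merged) == 1
        assert any(m.evidence_kind == "node" for m in merged[0].members)
        assert merged[0].position == 5000  # attachment does not move the position

    def test_node_on_wrong_side_stays_separate(self):
        clusters = cluster_evidence([_hit("a", 5000)], window=100)
        node = _hit("n1", 5400, kind="node", side="right")  # cluster is behind it
        merged = attach_nodes(clusters, [node], max_dist=700, window=100)
        assert len(merged) == 2

    def test_orphan_nodes_form_their_own_cluster(self):
        merged = attach_nodes([], [_hit("n1", 800, kind="node", side="right"),
                                   _hit("n2", 820, kind="node", side="right")],
                              max_dist=700, window=100)
        assert len(merged) == 1 and len(merged[0].members) == 2


class TestConfidence:
    def _cluster(self, n):
        return EvidenceCluster(
            chrom="chr1", position=100,
            members=[_hit(f"e{i}", 100 + i) for i in range(n)],
        )

    @pytest.mark.parametrize("n,expected", [(3, "HC"), (2, "LC"), (1, "LC"), (5, "HC")])
    def test_three_or_more_supports_is_high_confidence(self, n, expected):
        assert assign_confidence(self._cluster(n)).confidence == expected

    def test_duplicate_evidence_counts_once(self):
        cl = EvidenceCluster(
            chrom="chr1", position=100,
            members=[_hit("same", 100), _hit("same", 101), _hit("other", 102)],
        )
        locus = assign_confidence(cl)
        assert locus.support.total == 2 and locus.confidence == "LC"

    def test_support_counts_by_kind(self):
        cl = EvidenceCluster(
            chrom="chr1", position=100,
            members=[_hit("a", 100, "hybrid_LE"), _hit("b", 101, "hybrid_RE"),
                     _hit("c", 102, "node", side="right")],
        )
        locus = assign_confidence(cl)
        assert (locus.support.hybrid_LE, locus.support.hybrid_RE, locus.support.node) == (1, 1, 1)
        assert locus.confidence == "HC"


def _locus(chrom, pos, confidence, support_total=3):
    sup = SupportCounts(hybrid_LE=support_total)
    return InsertionLocus(
        insertion_id="", chrom=chrom, position=pos, support=sup,
        confidence=confidence, evidence_ids=[f"{chrom}:{pos}"],
    )


class TestNumbering:
    def test_lc_numbered_after_hc(self):
        loci = [_locus("chr1", 500, "HC"), _locus("chr1", 100, "LC", 1), _locus("chr2", 9, "HC")]
        ordered = number_loci(loci, ["chr1", "chr2"])
        assert [lo.insertion_id for lo in ordered] == ["Insertion-1", "Insertion-2", "Insertion-3"]
        assert ordered[-1].confidence == "LC"

    def test_chromosome_order_before_position(self):
        loci = [_locus("chr2", 100, "HC"), _locus("chr1", 500, "HC")]
        ordered = number_loci(loci, ["chr1", "chr2"])
        assert (ordered[0].chrom, ordered[0].position) == ("chr1", 500)

    def test_single_locus_is_insertion_1(self):
        ordered = number_loci([_locus("chr1", 42, "HC")], ["chr1"])
        assert ordered[0].insertion_id == "Insertion-1"

    def test_scaffolds_sort_after_named_chromosomes(self):
        loci = [_locus("scaffold0007", 5, "HC"), _locus("chr2", 900, "HC")]
        ordered = number_loci(loci, ["chr1", "chr2"])
        assert ordered[0].chrom == "chr2"

    def test_numbering_is_pure_and_deterministic(self):
        loci = [_locus("chr1", p, "HC") for p in (300, 100, 200)]
        a = [lo.insertion_id for lo in number_loci(list(loci), ["chr1"])]
        b = [lo.insertion_id for lo in number_loci(list(reversed(loci)), ["chr1"])]
        assert a == b == ["Insertion-1", "Insertion-2", "Insertion-3"]


class TestZygosity:
    def _pairs(self, n, b):
        return [
            PlacedPair("chr1", b - 300 + i, b - 211 + i, b + 150 + i, b + 239 + i)
            for i in range(n)
        ]

    def test_no_spanning_with_support_is_homozygous(self):
        locus = _locus("chr1", 1000, "HC", support_total=5)
        out = estimate_zygosity(locus, [])
        assert out.zygosity == "homozygous" and out.spanning_pairs == 0

    def test_spanning_fragments_mean_heterozygous(self):
        locus = _locus("chr1", 1000, "HC", support_total=5)
        out = estimate_zygosity(locus, self._pairs(4, 1000))
        assert out.zygosity == "heterozygous" and out.spanning_pairs == 4

    def test_one_junction_read_one_spanning_pair_is_undetermined(self):
        locus = _locus("chr1", 1000, "LC", support_total=1)
        out = estimate_zygosity(locus, self._pairs(1, 1000))
        assert out.zygosity == "undetermined"

    def test_spanning_requires_opposite_sides(self):
        # both mates left of the breakpoint: not spanning
        pair = PlacedPair("chr1", 500, 589, 620, 709)
        assert count_spanning_pairs("chr1", 1000, [pair]) == 0
        # breakpoint inside the right mate: not "opposite sides"
        pair2 = PlacedPair("chr1", 500, 589, 950, 1039)
        assert count_spanning_pairs("chr1", 1000, [pair2]) == 0
        pair3 = PlacedPair("chr1", 500, 589, 1001, 1090)
        assert count_spanning_pairs("chr1", 1000, [pair3]) == 1


class TestMapEvidence:
    def _hybrid(self, frag, end="LE", side="left", rid="h1"):
        L = len(frag)
        return HybridRead(
            read_id=rid, end=end,
            element_interval=(L, L + 40), genomic_interval=(0, L),
            genomic_fragment=frag, junction_offset=L,
            element_side="right" if side == "left" else "left",
            strand="+",
        )

    def test_fragment_with_left_edge_junction_breakpoint(self, small_genome):
        # genomic fragment copied from positions p..p+49 (0-based p0) whose
        # junction sits at the fragment's left edge -> breakpoint p0+1
        name, seq = small_genome[0]
        idx = build_kmer_index(small_genome, k=13)
        p0 = 50_000
        frag = seq[p0 : p0 + 50]
        hy = HybridRead(
            read_id="h1", end="RE", element_interval=(0, 40),
            genomic_interval=(40, 90), genomic_fragment=frag,
            junction_offset=40, element_side="left", strand="+",
        )
        hits, report = map_evidence([hy], [], idx)
        assert report.mapped == 1
        assert hits[0].breakpoint == p0 + 1
        assert hits[0].evidence_kind == "hybrid_RE"

    def test_fragment_with_right_edge_junction_breakpoint(self, small_genome):
        name, seq = small_genome[0]
        idx = build_kmer_index(small_genome, k=13)
        p0 = 60_000
        frag = seq[p0 - 50 : p0]
        hy = HybridRead(
            read_id="h2", end="LE", element_interval=(50, 90),
            genomic_interval=(0, 50), genomic_fragment=frag,
            junction_offset=50, element_side="right", strand="+",
        )
        hits, _ = map_evidence([hy], [], idx)
        assert hits[0].breakpoint == p0  # 1-based last mapped base

    def test_duplicated_fragment_is_discarded_as_multimapper(self, small_genome):
        name, seq = small_genome[0]
        dup = seq[:10_000] + seq[5_000:5_200] + seq[10_000:]
        idx = build_kmer_index([("chr1", dup)], k=13)
        hy = self._hybrid(seq[5_050 : 5_100])
        hits, report = map_evidence([hy], [], idx)
        assert hits == [] and report.multimapped == 1

    def test_unmappable_fragment_counted(self, small_genome):
        idx = build_kmer_index(small_genome, k=13)
        hits, report = map_evidence([self._hybrid("ACGT" * 15)], [], idx)
        assert report.unmapped == 1 or report.multimapped == 1

    def test_node_breakpoint_at_element_facing_end(self, small_genome):
        name, seq = small_genome[0]
        idx = build_kmer_index(small_genome, k=13)
        node = ContigNode(
            node_id="n1", sequence=seq[30_000:30_400], k=21,
            support_reads=["r1"], anchor=NodeAnchor(end="LE", element_side="right"),
        )
        hits, _ = map_evidence([], [node], idx)
        assert hits[0].breakpoint == 30_400  # 1-based right end
        node.anchor = NodeAnchor(end="RE", element_side="left")
        hits, _ = map_evidence([], [node], idx)
        assert hits[0].breakpoint == 30_001

    def test_low_identity_fragment_rejected(self, small_genome):
        name, seq = small_genome[0]
        idx = build_kmer_index(small_genome, k=13)
        frag = list(seq[70_000:70_030])
        for i in range(0, 30, 4):  # heavy mutation -> identity < 0.9
            frag[i] = "A" if frag[i] != "A" else "C"
        hits, report = map_evidence([self._hybrid("".join(frag))], [], idx)
        assert hits == []


class TestEvidenceHitInvariant:
    def test_breakpoint_must_be_near_interval(self):
        with pytest.raises(ValueError):
            EvidenceHit("e", "node", "chr1", 10, "+", 100, 200, 1.0)
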