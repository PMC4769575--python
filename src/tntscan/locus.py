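"""Mapping junction evidence to the reference, clustering it into insertion
loci, confidence assignment, deterministic numbering and zygosity.

Evidence kinds
--------------
* ``hybrid_LE`` / ``hybrid_RE`` — the genomic portion of a junction read;
  its breakpoint is the junction-proximal end of the mapped interval and is
  base-accurate at low error rates.
* ``node`` — an assembled rescue-read contig. Its supporting reads are one
  insert-length away from the junction, so the contig's element-facing end
  under-shoots the breakpoint by up to the library insert size. Node
  evidence is therefore *attached* to the nearest junction cluster on its
  element-facing side (within an insert-scale distance) rather than being
  clustered by its own breakpoint; nodes with no cluster in range form
  node-only clusters, which in practice stay low-confidence.

A locus is high confidence (HC) when it has at least ``hc_min_support``
(default 3) distinct supporting reads/nodes, each counted once. Loci are
sorted HC before LC, then by chromosome (caller-supplied order, unplaced
scaffolds after chromosomes), then position, and numbered "Insertion-1",
"Insertion-2", ... in that order.

Zygosity comes from reference-spanning genomic (type 2) fragments: a
homozygous insertion interrupts both haplotypes so no fragment spans its
junction, while a heterozygous one leaves the reference haplotype intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .align import KmerIndex, Scoring, seeded_local_align
from .assemble import ContigNode
from .classify import HybridRead

DEFAULT_CLUSTER_WINDOW = 100
DEFAULT_HC_MIN_SUPPORT = 3
DEFAULT_MIN_SPAN = 3
DEFAULT_MIN_MAPPED_LEN = 20
DEFAULT_MIN_MAP_IDENTITY = 0.9
DEFAULT_MIN_MAP_COVERAGE = 0.8  # aligned fraction of the evidence sequence
DEFAULT_NODE_ATTACH_DIST = 700  # insert mean + 4 sd for the 500 +/- 50 design

EvidenceKind = Literal["hybrid_LE", "hybrid_RE", "node"]


@dataclass(slots=True)
class EvidenceHit:
    evidence_id: str
    evidence_kind: EvidenceKind
    chrom: str
    breakpoint: int  # 1-based inferred junction coordinate
    strand: str
    mapped_start: int  # 0-based half-open reference interval
    mapped_end: int
    identity: float
    element_side: Literal["left", "right", ""] = ""  # for node evidence

    def __post_init__(self) -> None:
        if not (self.mapped_start <= self.breakpoint <= self.mapped_end + 1):
            raise ValueError("breakpoint must lie within or adjacent to the mapped interval")


@dataclass(slots=True)
class MappingReport:
    mapped: int = 0
    unmapped: int = 0
    multimapped: int = 0


@dataclass(slots=True)
class EvidenceCluster:
    chrom: str
    position: int  # 1-based representative junction coordinate
    members: list[EvidenceHit]


@dataclass(slots=True)
class SupportCounts:
    hybrid_LE: int = 0
    hybrid_RE: int = 0
    node: int = 0

    @property
    def total(self) -> int:
        return self.hybrid_LE + self.hybrid_RE + self.node


@dataclass(slots=True)
class InsertionLocus:
    insertion_id: str
    chrom: str
    position: int
    support: SupportCounts
    confidence: Literal["HC", "LC"]
    zygosity: Literal["homozygous", "heterozygous", "undetermined"] = "undetermined"
    spanning_pairs: int = 0
    evidence_ids: list[str] = field(default_factory=list)


@dataclass(slots=True)
class PlacedPair:
    """A genomic (type 2) pair placed on the reference; 1-based closed
    intervals for each mate, left interval first."""

    chrom: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int


def _best_unique_hit(hits, min_identity, min_mapped_len, query_len, min_coverage):
    """Best-scoring hit, or ('multi', None) when several locations tie.

    Requiring the alignment to cover most of the evidence sequence (not just
    an absolute minimum) rejects short chance matches of foreign sequence —
    e.g. element-interior fragments from mis-split reads, whose ~20 bp
    seed-extension hits would otherwise pile up at one reference locus."""
    hits = [
        h
        for h in hits
        if h.identity >= min_identity
        and (h.target_end - h.target_start) >= min_mapped_len
        and h.query_span >= min_coverage * query_len
    ]
    if not hits:
        return "unmapped", None
    best_score = max(h.score for h in hits)
    best = [h for h in hits if h.score == best_score]
    if len(best) > 1:
        return "multi", None
    return "ok", best[0]


def map_evidence(
    hybrids: Sequence[HybridRead],
    nodes: Sequence[ContigNode],
    genome_index: KmerIndex,
    min_identity: float = DEFAULT_MIN_MAP_IDENTITY,
    min_mapped_len: int = DEFAULT_MIN_MAPPED_LEN,
    min_coverage: float = DEFAULT_MIN_MAP_COVERAGE,
    scoring: Scoring | None = None,
) -> tuple[list[EvidenceHit], MappingReport]:
    """Align hybrid genomic fragments and contigs to the reference, keep
    uniquely-best placements covering most of the evidence sequence, and
    derive per-evidence breakpoints."""
    scoring = scoring or Scoring()
    report = MappingReport()
    out: list[EvidenceHit] = []
    min_score = max(5, int(min_mapped_len * 0.7))

    for hy in hybrids:
        if len(hy.genomic_fragment) < max(min_mapped_len, genome_index.k):
            report.unmapped += 1
            continue
        status, hit = _best_unique_hit(
            seeded_local_align(hy.genomic_fragment, genome_index, scoring, min_score=min_score),
            min_identity, min_mapped_len, len(hy.genomic_fragment), min_coverage,
        )
        if status == "multi":
            report.multimapped += 1
            continue
        if status == "unmapped":
            report.unmapped += 1
            continue
        # The junction abuts the element side of the fragment in read
        # orientation; map it through the hit strand to a reference end.
        junction_at_fragment_left = hy.element_side == "left"
        if hit.strand == "-":
            junction_at_fragment_left = not junction_at_fragment_left
        bp = hit.target_start + 1 if junction_at_fragment_left else hit.target_end
        report.mapped += 1
        out.append(
            EvidenceHit(
                evidence_id=hy.read_id,
                evidence_kind="hybrid_LE" if hy.end == "LE" else "hybrid_RE",
                chrom=hit.target_id,
                breakpoint=bp,
                strand=hit.strand,
                mapped_start=hit.target_start,
                mapped_end=hit.target_end,
                identity=hit.identity,
            )
        )

    for node in nodes:
        status, hit = _best_unique_hit(
            seeded_local_align(node.sequence, genome_index, scoring, min_score=min_score),
            min_identity, min_mapped_len, len(node.sequence), min_coverage,
        )
        if status == "multi":
            report.multimapped += 1
            continue
        if status == "unmapped":
            report.unmapped += 1
            continue
        side = node.anchor.element_side if node.anchor else "right"
        bp = hit.target_end if side == "right" else hit.target_start + 1
        report.mapped += 1
        out.append(
            EvidenceHit(
                evidence_id=node.node_id,
                evidence_kind="node",
                chrom=hit.target_id,
                breakpoint=bp,
                strand=hit.strand,
                mapped_start=hit.target_start,
                mapped_end=hit.target_end,
                identity=hit.identity,
                element_side=side,
            )
        )
    return out, report


def _lower_median(values: Sequence[int]) -> int:
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


def cluster_evidence(hits: Sequence[EvidenceHit], window: int = DEFAULT_CLUSTER_WINDOW) -> list[EvidenceCluster]:
    """Single-linkage clustering per chromosome: consecutive breakpoints
    join one cluster while the gap is <= window. Left- and right-junction
    evidence of one element (a few bp apart via the target-site duplication)
    merges into one cluster. Cluster position = lower median of member
    breakpoints."""
    ordered = sorted(hits, key=lambda h: (h.chrom, h.breakpoint, h.evidence_id))
    clusters: list[EvidenceCluster] = []
    current: list[EvidenceHit] = []
    for h in ordered:
        if current and (h.chrom != current[-1].chrom or h.breakpoint - current[-1].breakpoint > window):
            clusters.append(_finish_cluster(current))
            current = []
        current.append(h)
    if current:
        clusters.append(_finish_cluster(current))
    return clusters


def _finish_cluster(members: list[EvidenceHit]) -> EvidenceCluster:
    return EvidenceCluster(
        chrom=members[0].chrom,
        position=_lower_median([m.breakpoint for m in members]),
        members=list(members),
    )


def attach_nodes(
    clusters: list[EvidenceCluster],
    node_hits: Sequence[EvidenceHit],
    max_dist: int = DEFAULT_NODE_ATTACH_DIST,
    window: int = DEFAULT_CLUSTER_WINDOW,
) -> list[EvidenceCluster]:
    """Attach node evidence to the nearest cluster on the node's
    element-facing side within ``max_dist`` (with a small backward slack for
    alignment noise). Unattached nodes are clustered among themselves by
    their own breakpoints; cluster positions are not moved by attachment
    (hybrid breakpoints are base-accurate, node ends are not)."""
    leftovers: list[EvidenceHit] = []
    for nh in sorted(node_hits, key=lambda h: (h.chrom, h.breakpoint, h.evidence_id)):
        best = None
        best_dist = None
        for cl in clusters:
            if cl.chrom != nh.chrom:
                continue
            delta = cl.position - nh.breakpoint  # >0: cluster right of the node end
            if nh.element_side == "right":
                ok = -window <= delta <= max_dist
            else:
                ok = -max_dist <= delta <= window
            if ok:
                dist = abs(delta)
                if best is None or dist < best_dist or (dist == best_dist and cl.position < best.position):
                    best, best_dist = cl, dist
        if best is not None:
            best.members.append(nh)
        else:
            leftovers.append(nh)
    clusters = list(clusters)
    clusters.extend(cluster_evidence(leftovers, window=window))
    return clusters


def assign_confidence(
    cluster: EvidenceCluster, hc_min_support: int = DEFAULT_HC_MIN_SUPPORT
) -> InsertionLocus:
    """HC iff the cluster has >= hc_min_support distinct reads/nodes, each
    physical read or node counted once."""
    if not cluster.members:
        raise ValueError("cannot assign confidence to an empty cluster")
    support = SupportCounts()
    seen: set[str] = set()
    evidence_ids: list[str] = []
    for m in cluster.members:
        if m.evidence_id in seen:
            continue
        seen.add(m.evidence_id)
        evidence_ids.append(m.evidence_id)
        setattr(support, m.evidence_kind, getattr(support, m.evidence_kind) + 1)
    return InsertionLocus(
        insertion_id="",
        chrom=cluster.chrom,
        position=cluster.position,
        support=support,
        confidence="HC" if support.total >= hc_min_support else "LC",
        evidence_ids=sorted(evidence_ids),
    )


def number_loci(loci: Sequence[InsertionLocus], chrom_order: Sequence[str]) -> list[InsertionLocus]:
    """Sort HC before LC, then chromosome rank (names absent from
    ``chrom_order`` — unplaced scaffolds — after chromosomes, alphabetically),
    then ascending position; assign ids Insertion-1, Insertion-2, ... Ties on
    (confidence, chrom, position) break by descending support then first
    evidence id."""
    rank = {name: i for i, name in enumerate(chrom_order)}

    def key(locus: InsertionLocus):
        return (
            0 if locus.confidence == "HC" else 1,
            rank.get(locus.chrom, len(rank)),
            locus.chrom if locus.chrom not in rank else "",
            locus.position,
            -locus.support.total,
            locus.evidence_ids[0] if locus.evidence_ids else "",
        )

    ordered = sorted(loci, key=key)
    for i, locus in enumerate(ordered, start=1):
        locus.insertion_id = f"Insertion-{i}"
    return ordered


def count_spanning_pairs(
    chrom: str, breakpoint: int, pairs: Sequence[PlacedPair]
) -> int:
    """Fragments whose mates map to opposite sides of the breakpoint with
    the breakpoint strictly inside the implied fragment."""
    n = 0
    for p in pairs:
        if p.chrom != chrom:
            continue
        if (
            p.left_start < breakpoint < p.right_end
            and p.left_end <= breakpoint
            and p.right_start >= breakpoint
        ):
            n += 1
    return n


def estimate_zygosity(
    locus: InsertionLocus,
    pairs: Sequence[PlacedPair],
    min_span: int = DEFAULT_MIN_SPAN,
    hc_min_support: int = DEFAULT_HC_MIN_SUPPORT,
) -> InsertionLocus:
    """Homozygous: no spanning fragment and solid junction support.
    Heterozygous: >= min_span spanning fragments. Otherwise undetermined."""
    spanning = count_spanning_pairs(locus.chrom, locus.position, pairs)
    locus.spanning_pairs = spanning
    if spanning == 0 and locus.support.total >= hc_min_support:
        locus.zygosity = "homozygous"
    elif spanning >= min_span:
        locus.zygosity = "heterozygous"
    else:
        locus.zygosity = "undetermined"
    return locus


LOCUS_TSV_HEADER = (
    "insertion_id\tchrom\tposition\tconfidence\tsupport_total\t"
    "support_hybrid_LE\tsupport_hybrid_RE\tsupport_node\tzygosity\tspanning_pairs"
)


def loci_to_tsv(loci: Sequence[InsertionLocus]) -> str:
    lines = [LOCUS_TSV_HEADER]
    for lo in loci:
        lines.append(
            f"{lo.insertion_id}\t{lo.chrom}\t{lo.position}\t{lo.confidence}\t"
            f"{lo.support.total}\t{lo.support.hybrid_LE}\t{lo.support.hybrid_RE}\t"
            f"{lo.support.node}\t{lo.zygosity}\t{lo.spanning_pairs}"
        )
    return "\n".join(lines) + "\n"


def loci_to_bed(loci: Sequence[InsertionLocus]) -> str:
    """BED6: 0-based half-open single-base intervals, name=insertion_id,
    score=support_total."""
    lines = []
    for lo in loci:
        lines.append(
            f"{lo.chrom}\t{lo.position - 1}\t{lo.position}\t{lo.insertion_id}\t"
            f"{lo.support.total}\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")
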