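"""Contig ("node") assembly from rescue reads.

The genomic mates of type 4 and type 5 pairs tile the flank adjacent to each
insertion junction; assembling them into unitigs extends the junction
evidence beyond single-read length. The assembler is a plain de Bruijn
unitig builder: k-mers with canonical count >= ``min_kmer_count`` form the
graph (both orientations of every passing canonical k-mer are inserted, so
the graph is reverse-complement symmetric), maximal non-branching paths are
emitted, dead-end tips shorter than 2k attached to a branch are clipped, and
the resulting unitigs are deduplicated up to reverse complement. Output
order is lexicographic by canonical sequence, so assembly is deterministic.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Literal, Sequence

from .align import reverse_complement
from .classify import ClassifiedPair, LE
from .core_io import SequencingRead

DEFAULT_K = 21
DEFAULT_MIN_KMER_COUNT = 2

Side = Literal["left", "right"]  # which side of the read the element lies on, in reference coords


@dataclass(slots=True)
class NodeAnchor:
    """Pair-type context inherited from the mates that recruited the reads:
    the element end (LE/RE) the mates hit, and on which side of the contig
    the element must lie in reference orientation."""

    end: str
    element_side: Side


@dataclass(slots=True)
class ContigNode:
    node_id: str
    sequence: str
    k: int
    support_reads: list[str]
    anchor: NodeAnchor | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < self.k:
            raise ValueError("contig shorter than k")
        if not self.support_reads:
            raise ValueError("contig must have supporting reads")


@dataclass(slots=True)
class RescueRead:
    """A genomic mate recruited by an element/hybrid mate."""

    read: SequencingRead
    end: str  # LE or RE from the recruiting mate's terminal hit
    element_side: Side


def collect_rescue_reads(classified: Sequence[ClassifiedPair]) -> dict[str, list[RescueRead]]:
    """Group the genomic mates of type 4 and 5 pairs by the element end
    (LE/RE) implied by the recruiting mate's terminal hit.

    Read 1 of a pair is the fragment's 5' read and read 2 the reverse
    complement of its 3' end, so when the genomic mate is read 1 the element
    lies to its right in reference coordinates, and to its left when it is
    read 2. Hybrid mates of type 4 pairs are junction evidence in their own
    right and are routed to the hybrid stream, not collected here.
    """
    groups: dict[str, list[RescueRead]] = {LE: [], "RE": []}
    for cp in classified:
        if cp.pair_type not in (4, 5):
            continue
        if cp.class1.label == "genomic":
            genomic_read, recruiting = cp.pair.read1, cp.class2
            side: Side = "right"
        else:
            genomic_read, recruiting = cp.pair.read2, cp.class1
            side = "left"
        end = recruiting.end or LE
        groups[end].append(RescueRead(read=genomic_read, end=end, element_side=side))
    return groups


def _canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def assemble_nodes(
    reads: Sequence[SequencingRead | str],
    k: int = DEFAULT_K,
    min_kmer_count: int = DEFAULT_MIN_KMER_COUNT,
    node_prefix: str = "node",
) -> list[ContigNode]:
    """Assemble reads into unitigs (maximal non-branching de Bruijn paths).

    Reads shorter than k are ignored; an empty k-mer set yields an empty
    list. ``support_reads`` of each contig lists every read contributing at
    least one of its k-mers.
    """
    if not (15 <= k <= 31) or k % 2 == 0:
        raise ValueError("k must be odd and within [15, 31]")
    seqs: list[tuple[str, str]] = []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            seqs.append((f"read{i}", r.upper()))
        else:
            seqs.append((r.read_id, r.sequence))
    counts: Counter[str] = Counter()
    observed: Counter[str] = Counter()  # as-read orientation, for output strand
    support: dict[str, set[str]] = defaultdict(set)
    for rid, seq in seqs:
        if len(seq) < k:
            continue
        for j in range(len(seq) - k + 1):
            kmer = seq[j : j + k]
            if "N" in kmer:
                continue
            canon = _canonical(kmer)
            counts[canon] += 1
            observed[kmer] += 1
            support[canon].add(rid)
    passing: set[str] = set()
    for canon, c in counts.items():
        if c >= min_kmer_count:
            passing.add(canon)
            passing.add(reverse_complement(canon))
    unitigs = _emit_unitigs(passing, k)
    unitigs = _clip_tips(unitigs, passing, k)
    out: list[ContigNode] = []
    seen: set[str] = set()
    for seq in unitigs:
        rc_seq = reverse_complement(seq)
        canon_seq = min(seq, rc_seq)
        if canon_seq in seen:
            continue
        seen.add(canon_seq)
        readers: set[str] = set()
        for j in range(len(canon_seq) - k + 1):
            readers |= support.get(_canonical(canon_seq[j : j + k]), set())
        # orient the contig with the majority of as-read k-mer observations
        # (ties fall back to the lexicographically smaller strand)
        canon_rc = reverse_complement(canon_seq)
        fwd_obs = sum(observed.get(canon_seq[j : j + k], 0) for j in range(len(canon_seq) - k + 1))
        rev_obs = sum(observed.get(canon_rc[j : j + k], 0) for j in range(len(canon_rc) - k + 1))
        oriented = canon_rc if rev_obs > fwd_obs else canon_seq
        out.append(
            ContigNode(
                node_id="",
                sequence=oriented,
                k=k,
                support_reads=sorted(readers),
            )
        )
    out.sort(key=lambda n: min(n.sequence, reverse_complement(n.sequence)))
    for i, node in enumerate(out, start=1):
        node.node_id = f"{node_prefix}-{i}"
    return out


def _successors(kmer: str, kmers: set[str]) -> list[str]:
    suffix = kmer[1:]
    return [suffix + b for b in "ACGT" if suffix + b in kmers]


def _predecessors(kmer: str, kmers: set[str]) -> list[str]:
    prefix = kmer[:-1]
    return [b + prefix for b in "ACGT" if b + prefix in kmers]


def _emit_unitigs(kmers: set[str], k: int) -> list[str]:
    """Maximal non-branching paths over the k-mer adjacency graph. Internal
    vertices of every emitted path have in-degree and out-degree exactly 1."""
    unitigs: list[str] = []
    visited: set[str] = set()

    def is_path_start(km: str) -> bool:
        preds = _predecessors(km, kmers)
        if len(preds) != 1:
            return True
        return len(_successors(preds[0], kmers)) > 1

    for km in sorted(kmers):
        if km in visited or not is_path_start(km):
            continue
        path = [km]
        visited.add(km)
        cur = km
        while True:
            succs = _successors(cur, kmers)
            if len(succs) != 1:
                break
            nxt = succs[0]
            if len(_predecessors(nxt, kmers)) != 1 or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        unitigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    # isolated cycles: every vertex has in=out=1; walk each once
    for km in sorted(kmers):
        if km in visited:
            continue
        path = [km]
        visited.add(km)
        cur = km
        while True:
            succs = _successors(cur, kmers)
            nxt = succs[0]
            if nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            cur = nxt
        unitigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    return unitigs


def _clip_tips(unitigs: list[str], kmers: set[str], k: int) -> list[str]:
    """Drop dead-end unitigs shorter than 2k whose other end attaches to a
    branching vertex (sequencing-error spurs); isolated unitigs are kept."""
    kept: list[str] = []
    removed_kmers: set[str] = set()
    for seq in unitigs:
        if len(seq) >= 2 * k:
            kept.append(seq)
            continue
        first, last = seq[:k], seq[len(seq) - k :]
        dangling_start = len(_predecessors(first, kmers)) == 0
        dangling_end = len(_successors(last, kmers)) == 0
        attached = (not dangling_start) or (not dangling_end)
        if dangling_start and dangling_end:
            kept.append(seq)  # isolated contig, keep regardless of length
        elif attached and (dangling_start or dangling_end):
            for j in range(len(seq) - k + 1):
                removed_kmers.add(seq[j : j + k])
                removed_kmers.add(reverse_complement(seq[j : j + k]))
        else:
            kept.append(seq)
    if not removed_kmers:
        return kept
    return _emit_unitigs(kmers - removed_kmers, k)


def assemble_rescue_groups(
    groups: dict[str, list[RescueRead]],
    k: int = DEFAULT_K,
    min_kmer_count: int = DEFAULT_MIN_KMER_COUNT,
) -> list[ContigNode]:
    """Assemble each LE/RE group separately and anchor every contig with the
    end and the majority element side of its supporting reads."""
    nodes: list[ContigNode] = []
    for end in sorted(groups):
        rescue = groups[end]
        if not rescue:
            continue
        side_by_read: dict[str, Side] = {rr.read.read_id: rr.element_side for rr in rescue}
        assembled = assemble_nodes(
            [rr.read for rr in rescue], k=k, min_kmer_count=min_kmer_count,
            node_prefix=f"node-{end}",
        )
        for node in assembled:
            votes = Counter(side_by_read[rid] for rid in node.support_reads if rid in side_by_read)
            side: Side = "right"
            if votes and votes.most_common(1)[0][0] == "left":
                side = "left"
            node.anchor = NodeAnchor(end=end, element_side=side)
            nodes.append(node)
    return nodes


def nodes_to_fasta(nodes: Sequence[ContigNode]) -> str:
    """FASTA export with support counts encoded in headers."""
    out = []
    for n in nodes:
        anchor = f" end={n.anchor.end} side={n.anchor.element_side}" if n.anchor else ""
        out.append(f">{n.node_id} support={len(n.support_reads)}{anchor}\n{n.sequence}\n")
    return "".join(out)
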