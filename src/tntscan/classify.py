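"""Read classification against transposon terminal baits and the five-way
pair taxonomy.

Each read is aligned (both strands) to the element's left-end (LE) and
right-end (RE) terminal sequences and labelled:

* ``hybrid``  — a terminal-bait hit anchored at the element's outward edge
  (position 0 of the left end, or the last position of the right end),
  spanning at least ``min_element_match`` bases at ``min_identity`` and
  leaving a genomic tail of at least ``min_genomic_tail`` bases. These
  reads span an element-genome junction.
* ``element`` — the read matches the full element end-to-end (within a
  small slack) at any interior position, on either strand; reads lying
  wholly inside an LTR fall here because the two LTR copies are identical.
* ``genomic`` — everything else.

The ``end`` of an element-labelled read (which element end, LE or RE, its
fragment can adjoin) follows from its position within the element: hits in
the left half imply LE, in the right half RE — for a ~500 bp fragment the
recruiting mate always sits within one insert length of the junction, so
the half is unambiguous.

Mate labels combine into pair types 1-5: (element, element) -> 1,
(genomic, genomic) -> 2, hybrid with element -> 3, hybrid with genomic -> 4,
genomic with element -> 5. The taxonomy has no slot for two hybrids in one
pair; that combination is recorded as type 3 and both junctions kept as
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .align import (
    AlignmentHit,
    KmerIndex,
    Scoring,
    reverse_complement,
    rolling_kmers,
    seeded_local_align,
    encode,
)
from .core_io import ReadPair, SequencingRead, TransposonReference

LE = "LE"
RE = "RE"

DEFAULT_MIN_ELEMENT_MATCH = 15
DEFAULT_MIN_IDENTITY = 0.9
DEFAULT_MIN_GENOMIC_TAIL = 20
DEFAULT_FULL_MATCH_SLACK = 3
DEFAULT_TERMINAL_K = 11


@dataclass(slots=True)
class ReadClass:
    label: Literal["element", "genomic", "hybrid"]
    element_hit: AlignmentHit | None = None
    end: str | None = None  # LE or RE for element/hybrid labels

    def __post_init__(self) -> None:
        if self.label in ("element", "hybrid") and self.element_hit is None:
            raise ValueError(f"label {self.label!r} requires an element hit")
        if self.label == "genomic" and self.element_hit is not None:
            raise ValueError("genomic label must not carry an element hit")


@dataclass(slots=True)
class HybridRead:
    """A junction-spanning read split into element and genomic portions.

    Intervals are 0-based half-open in read orientation and partition the
    read exactly (any small unmatched stub at the read's outer edge is
    absorbed into the element interval). ``element_side`` records whether the
    element portion sits at the 'left' or 'right' end of the read as stored,
    and ``strand`` is the strand of the terminal hit; together with ``end``
    these determine which insertion junction the read supports.
    """

    read_id: str
    end: str  # LE or RE
    element_interval: tuple[int, int]
    genomic_interval: tuple[int, int]
    genomic_fragment: str
    junction_offset: int
    element_side: Literal["left", "right"]
    strand: str


class TerminalBaits:
    """Cached per-element alignment machinery for classification."""

    def __init__(self, tn: TransposonReference, k: int = DEFAULT_TERMINAL_K):
        self.tn = tn
        self.k = k
        self.index = KmerIndex([(LE, tn.left_terminal), (RE, tn.right_terminal)], k=k)
        self.element_index = KmerIndex([("element", tn.sequence)], k=k)
        self.element_rc = reverse_complement(tn.sequence)
        # packed k-mers of the whole element, both strands, for the prefilter
        vals = []
        for seq in (tn.sequence, self.element_rc):
            kv, valid = rolling_kmers(encode(seq), k)
            vals.append(kv[valid])
        self.bait_kmers = np.unique(np.concatenate(vals))


_BAIT_CACHE: dict[int, TerminalBaits] = {}


def _baits_for(tn: TransposonReference, k: int = DEFAULT_TERMINAL_K) -> TerminalBaits:
    key = id(tn) * 100 + k
    baits = _BAIT_CACHE.get(key)
    if baits is None or baits.tn is not tn:
        baits = TerminalBaits(tn, k)
        _BAIT_CACHE.clear()  # one element per pipeline run; avoid unbounded growth
        _BAIT_CACHE[key] = baits
    return baits


def _sorted_membership(values: np.ndarray, sorted_set: np.ndarray) -> np.ndarray:
    """Membership of ``values`` in a pre-sorted array (np.isin re-hashes the
    set on every call, which dominates per-read classification cost)."""
    if len(sorted_set) == 0 or values.size == 0:
        return np.zeros(values.shape, dtype=bool)
    idx = np.searchsorted(sorted_set, values)
    idx = np.minimum(idx, len(sorted_set) - 1)
    return sorted_set[idx] == values


def _best_terminal_hit(
    sequence: str, baits: TerminalBaits, min_score: int
) -> AlignmentHit | None:
    hits = seeded_local_align(sequence, baits.index, Scoring(), min_score=min_score)
    if not hits:
        return None
    # deterministic preference: score desc, then LE before RE, + before -,
    # then smaller query start
    return min(hits, key=lambda h: (-h.score, h.target_id != LE, h.strand, h.query_start))


def _end_from_element_position(tn: TransposonReference, t_start: int, t_end: int) -> str:
    """Which element end a fully-internal match implies: left half -> LE."""
    return LE if (t_start + t_end) / 2 < len(tn.sequence) / 2 else RE


def _exact_element_hit(seq: str, baits: TerminalBaits) -> AlignmentHit | None:
    """Fast path: the read (or its reverse complement) is an exact substring
    of the element — by far the common case for element-derived reads at low
    error rates."""
    L = len(seq)
    pos = baits.tn.sequence.find(seq)
    strand = "+"
    if pos < 0:
        pos_rc = baits.element_rc.find(seq)
        if pos_rc < 0:
            return None
        pos = len(baits.tn.sequence) - pos_rc - L
        strand = "-"
    return AlignmentHit(
        query_id="read", target_id="element",
        query_start=0, query_end=L,
        target_start=pos, target_end=pos + L,
        strand=strand, score=L, identity=1.0,
    )


def classify_read(
    read: SequencingRead | str,
    tn: TransposonReference,
    min_element_match: int = DEFAULT_MIN_ELEMENT_MATCH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_genomic_tail: int = DEFAULT_MIN_GENOMIC_TAIL,
    full_match_slack: int = DEFAULT_FULL_MATCH_SLACK,
    terminal_k: int = DEFAULT_TERMINAL_K,
) -> ReadClass:
    """Label one read as element / hybrid / genomic.

    Order of checks: exact full-element substring (element), anchored
    terminal-bait split (hybrid), near-full element match tolerating errors
    (element), otherwise genomic.
    """
    seq = read if isinstance(read, str) else read.sequence
    baits = _baits_for(tn, terminal_k)
    L = len(seq)

    exact = _exact_element_hit(seq, baits)
    if exact is not None:
        return ReadClass(
            label="element", element_hit=exact,
            end=_end_from_element_position(tn, exact.target_start, exact.target_end),
        )

    min_score = max(min(min_element_match - 2, 10), 5)
    hit = _best_terminal_hit(seq, baits, min_score=min_score)
    hybrid_candidate = False
    if hit is not None:
        anchored = (hit.target_id == LE and hit.target_start == 0) or (
            hit.target_id == RE and hit.target_end == tn.terminal_length
        )
        covered = hit.query_span
        outer_stub = min(hit.query_start, L - hit.query_end)
        tail = max(hit.query_start, L - hit.query_end)
        hybrid_candidate = (
            anchored
            and covered >= min_element_match
            and hit.identity >= min_identity
            and outer_stub <= full_match_slack
            and tail >= min_genomic_tail
        )

    # Full-element arbitration. A read with a sequencing error that lies
    # wholly inside the element (e.g. straddling the internal LTR-interior
    # boundary, where the terminal's outward edge recurs) can satisfy the
    # anchored-split conditions; if the read matches the whole element
    # end-to-end it is element, never hybrid. The seed-count gate skips
    # chance single-k-mer genomic reads; hybrid candidates (few) are always
    # checked.
    kv, valid = rolling_kmers(encode(seq), baits.k)
    n_seeds = int(np.count_nonzero(_sorted_membership(kv[valid], baits.bait_kmers)))
    if hybrid_candidate or n_seeds >= max(1, (L - baits.k + 1) // 4):
        full_hits = seeded_local_align(
            seq, baits.element_index, Scoring(), min_score=max(L // 2, min_score)
        )
        if full_hits:
            best = min(full_hits, key=lambda h: (-h.score, h.query_start, h.target_start, h.strand))
            if L - best.query_span <= full_match_slack and best.identity >= min_identity:
                return ReadClass(
                    label="element", element_hit=best,
                    end=_end_from_element_position(tn, best.target_start, best.target_end),
                )
    if hybrid_candidate:
        return ReadClass(label="hybrid", element_hit=hit, end=hit.target_id)
    return ReadClass(label="genomic")


def classify_pair(c1: ReadClass, c2: ReadClass) -> int:
    """Map two read labels onto the five pair types (order-insensitive)."""
    labels = frozenset((c1.label, c2.label)) if c1.label != c2.label else (c1.label,)
    if labels == ("element",):
        return 1
    if labels == ("genomic",):
        return 2
    if labels == ("hybrid",):
        return 3  # two junction reads in one pair; both kept as evidence
    if labels == frozenset(("hybrid", "element")):
        return 3
    if labels == frozenset(("hybrid", "genomic")):
        return 4
    if labels == frozenset(("genomic", "element")):
        return 5
    raise AssertionError(f"unreachable label combination {labels!r}")


def extract_hybrid(read: SequencingRead | str, cls: ReadClass, read_id: str | None = None) -> HybridRead:
    """Split a hybrid-labelled read into its element and genomic portions."""
    if cls.label != "hybrid":
        raise ValueError(f"extract_hybrid called on a {cls.label!r} read")
    seq = read if isinstance(read, str) else read.sequence
    if read_id is None:
        read_id = "read" if isinstance(read, str) else read.read_id
    hit = cls.element_hit
    assert hit is not None
    L = len(seq)
    left_rest = hit.query_start
    right_rest = L - hit.query_end
    if left_rest >= right_rest:
        # genomic portion on the left of the read; element absorbs the outer stub
        element_iv = (hit.query_start, L)
        genomic_iv = (0, hit.query_start)
        side: Literal["left", "right"] = "right"
        junction = hit.query_start
    else:
        element_iv = (0, hit.query_end)
        genomic_iv = (hit.query_end, L)
        side = "left"
        junction = hit.query_end
    return HybridRead(
        read_id=read_id,
        end=cls.end or "",
        element_interval=element_iv,
        genomic_interval=genomic_iv,
        genomic_fragment=seq[genomic_iv[0] : genomic_iv[1]],
        junction_offset=junction,
        element_side=side,
        strand=hit.strand,
    )


@dataclass(slots=True)
class ClassifiedPair:
    pair: ReadPair
    class1: ReadClass
    class2: ReadClass
    pair_type: int


def candidate_mask(sequences: Sequence[str], baits: TerminalBaits) -> np.ndarray:
    """Vectorised prefilter: True where a read shares at least one exact
    k-mer with a terminal bait on either strand — exactly the condition for
    the seeded aligner to produce any seed. Non-candidates are genomic."""
    n = len(sequences)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    lens = {len(s) for s in sequences}
    k = baits.k
    if len(lens) == 1:
        (L,) = lens
        if L < k:
            return mask
        n_win = L - k + 1
        chunk = max(1, 30_000_000 // (8 * n_win))  # bound transient memory
        for start in range(0, n, chunk):
            block = sequences[start : start + chunk]
            codes = encode("".join(block)).reshape(len(block), L)
            vals = np.zeros((len(block), n_win), dtype=np.uint64)
            invalid = np.zeros((len(block), n_win), dtype=bool)
            c = np.where(codes == 4, 0, codes).astype(np.uint64)
            n_mask = codes == 4
            for j in range(k):
                vals = vals * np.uint64(4) + c[:, j : j + n_win]
                invalid |= n_mask[:, j : j + n_win]
            present = _sorted_membership(vals, baits.bait_kmers) & ~invalid
            mask[start : start + chunk] = np.any(present, axis=1)
        return mask
    for i, s in enumerate(sequences):  # mixed read lengths: per-read fallback
        if len(s) < k:
            continue
        kv, valid = rolling_kmers(encode(s), k)
        mask[i] = bool(np.any(_sorted_membership(kv[valid], baits.bait_kmers)))
    return mask


def classify_pairs(
    pairs: Iterable[ReadPair],
    tn: TransposonReference,
    min_element_match: int = DEFAULT_MIN_ELEMENT_MATCH,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_genomic_tail: int = DEFAULT_MIN_GENOMIC_TAIL,
    full_match_slack: int = DEFAULT_FULL_MATCH_SLACK,
    terminal_k: int = DEFAULT_TERMINAL_K,
) -> list[ClassifiedPair]:
    """Classify every pair, using the batch k-mer prefilter to skip the
    (vast) genomic majority, then the full per-read rules on candidates."""
    pairs = list(pairs)
    baits = _baits_for(tn, terminal_k)
    seqs: list[str] = []
    for p in pairs:
        seqs.append(p.read1.sequence)
        seqs.append(p.read2.sequence)
    mask = candidate_mask(seqs, baits)
    genomic = ReadClass(label="genomic")
    out: list[ClassifiedPair] = []
    kwargs = dict(
        min_element_match=min_element_match,
        min_identity=min_identity,
        min_genomic_tail=min_genomic_tail,
        full_match_slack=full_match_slack,
        terminal_k=terminal_k,
    )
    for i, p in enumerate(pairs):
        c1 = classify_read(p.read1, tn, **kwargs) if mask[2 * i] else genomic
        c2 = classify_read(p.read2, tn, **kwargs) if mask[2 * i + 1] else genomic
        out.append(ClassifiedPair(pair=p, class1=c1, class2=c2, pair_type=classify_pair(c1, c2)))
    return out


def pair_type_counts(classified: Sequence[ClassifiedPair]) -> dict[int, int]:
    counts = {t: 0 for t in (1, 2, 3, 4, 5)}
    for cp in classified:
        counts[cp.pair_type] += 1
    return counts


def classification_table(classified: Sequence[ClassifiedPair]) -> str:
    """Per-pair TSV: pair_id, type, read1_label, read2_label."""
    lines = ["pair_id\ttype\tread1_label\tread2_label"]
    for cp in classified:
        lines.append(f"{cp.pair.pair_id}\t{cp.pair_type}\t{cp.class1.label}\t{cp.class2.label}")
    return "\n".join(lines) + "\n"


def hybrids_to_fasta(hybrids: Sequence[HybridRead]) -> str:
    """Genomic fragments of hybrid reads as FASTA, with the element end,
    junction offset and strand encoded in the headers."""
    out = []
    for hy in hybrids:
        out.append(
            f">{hy.read_id} end={hy.end} junction={hy.junction_offset} "
            f"side={hy.element_side} strand={hy.strand}\n{hy.genomic_fragment}\n"
        )
    return "".join(out)


def collect_hybrids(classified: Sequence[ClassifiedPair]) -> list[HybridRead]:
    """Extract every hybrid-labelled read (from type 3 and 4 pairs, and from
    double-hybrid pairs recorded as type 3)."""
    hybrids: list[HybridRead] = []
    for cp in classified:
        for read, cls in ((cp.pair.read1, cp.class1), (cp.pair.read2, cp.class2)):
            if cls.label == "hybrid":
                hybrids.append(extract_hybrid(read, cls))
    return hybrids
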