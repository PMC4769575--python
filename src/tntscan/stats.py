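"""Companion statistics: flanking-sequence-tag (FST) deduplication and
overlap, Mendelian segregation chi-square, and fold-coverage estimation.

FSTs are short genomic sequences flanking an insertion; two mapped records
within a small window on the same chromosome are treated as the same
insertion. The segregation test is the plain Pearson goodness-of-fit against
an expected ratio (default 3:1 wild-type:mutant, the single-recessive-locus
expectation), with no continuity correction. Fold coverage follows the
clean-bases / genome-size convention, reported floored alongside the
unrounded ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.stats import chi2 as _chi2_dist

DEFAULT_FST_WINDOW = 100  # same "same insertion" tolerance as locus clustering


@dataclass(slots=True)
class FstRecord:
    source: str  # e.g. TAIL_R0, TAIL_R1, TAIL_BC1F2, WGS
    chrom: str  # reference name or "unmapped"
    position: int | None = None  # 1-based, None iff unmapped
    sequence: str | None = None  # optional, used to compare unmapped records

    def __post_init__(self) -> None:
        mapped = self.chrom != "unmapped"
        if mapped != (self.position is not None):
            raise ValueError("position must be present exactly when chrom != 'unmapped'")


@dataclass(slots=True)
class SegregationTable:
    n_wildtype: int
    n_mutant: int
    expected_ratio: tuple[int, int] = (3, 1)

    def __post_init__(self) -> None:
        if self.n_wildtype < 0 or self.n_mutant < 0:
            raise ValueError("counts must be non-negative")
        a, b = self.expected_ratio
        if a <= 0 or b <= 0:
            raise ValueError("expected ratio terms must be positive")


def _same_site(a: FstRecord, b: FstRecord, window: int) -> bool:
    if a.chrom == "unmapped" or b.chrom == "unmapped":
        if a.chrom == "unmapped" and b.chrom == "unmapped":
            return a.sequence is not None and a.sequence == b.sequence
        return False
    return a.chrom == b.chrom and abs(a.position - b.position) <= window


def dedup_fsts(
    records: Sequence[FstRecord], window: int = DEFAULT_FST_WINDOW
) -> tuple[list[FstRecord], dict[str, int]]:
    """Collapse records marking the same insertion site (single linkage
    within ``window``); report per-source novelty.

    Processing records in the given order, a record is *novel* when no record
    from an earlier source matches it (and it is not redundant with an
    earlier record of its own source). The returned unique list keeps one
    representative per cluster (the earliest record, in input order).
    Unmapped records compare by exact sequence identity when sequences are
    supplied, otherwise they stay distinct.
    """
    uniques: list[FstRecord] = []
    clusters: list[list[FstRecord]] = []
    source_order: list[str] = []
    novelty: dict[str, int] = {}
    for rec in records:
        if rec.source not in novelty:
            novelty[rec.source] = 0
            source_order.append(rec.source)
        matching = [ci for ci, cl in enumerate(clusters) if any(_same_site(rec, m, window) for m in cl)]
        earlier_sources = set(source_order[: source_order.index(rec.source)])
        earlier_match = any(
            m.source in earlier_sources for ci in matching for m in clusters[ci]
        )
        if not earlier_match and not any(
            m.source == rec.source for ci in matching for m in clusters[ci]
        ):
            novelty[rec.source] += 1
        if matching:
            # single linkage: merge every cluster the record touches
            merged = [m for ci in matching for m in clusters[ci]] + [rec]
            clusters = [cl for ci, cl in enumerate(clusters) if ci not in matching]
            clusters.append(merged)
        else:
            clusters.append([rec])
    uniques = [cl[0] for cl in clusters]
    return uniques, novelty


def overlap_sets(
    a: Sequence[FstRecord], b: Sequence[FstRecord], window: int = DEFAULT_FST_WINDOW
) -> tuple[int, int, int]:
    """(|a only|, |b only|, |shared|) under greedy nearest-first one-to-one
    matching within ``window``. Both sets are assumed internally
    deduplicated; the counts partition |a| + |b| - |shared|."""
    candidates = []
    for i, ra in enumerate(a):
        for j, rb in enumerate(b):
            if _same_site(ra, rb, window):
                dist = (
                    abs(ra.position - rb.position)
                    if ra.chrom != "unmapped"
                    else 0
                )
                candidates.append((dist, i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = 0
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared += 1
    return len(a) - shared, len(b) - shared, shared


def chi_square_segregation(table: SegregationTable) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of observed (wild-type, mutant) counts against
    the expected ratio; returns (chi2, df=1, upper-tail p). No continuity
    correction."""
    total = table.n_wildtype + table.n_mutant
    if total == 0:
        raise ValueError("segregation table has zero total count")
    a, b = table.expected_ratio
    exp_wt = total * a / (a + b)
    exp_mut = total * b / (a + b)
    stat = (table.n_wildtype - exp_wt) ** 2 / exp_wt + (table.n_mutant - exp_mut) ** 2 / exp_mut
    df = 1
    p = float(_chi2_dist.sf(stat, df))
    return float(stat), df, p


def coverage_estimate(clean_bases: float, genome_size: float) -> tuple[int, float]:
    """Fold coverage = clean bases / genome size: (floored fold, raw ratio)."""
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    ratio = clean_bases / genome_size
    return int(ratio), float(ratio)
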