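"""End-to-end detection pipeline: QC -> classify -> assemble -> map ->
cluster -> confidence -> zygosity -> numbering.

The pipeline is deterministic: identical inputs and configuration produce
byte-identical output tables. Zygosity uses a fast vectorised placement of
genomic-genomic (type 2) pairs: each mate is anchored by an exact seed
k-mer with a unique genome position (a few fixed offsets are tried so a
sequencing error in one window does not lose the read), which is exact for
the uniquely-placeable reads that matter near junctions.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import align, assemble, classify, core_io, locus as locus_mod
from .config import PipelineConfig

logger = logging.getLogger("tntscan")


@dataclass
class DetectionResult:
    loci: list[locus_mod.InsertionLocus]
    qc_report: core_io.QcReport
    pair_type_counts: dict[int, int]
    n_hybrids: int
    n_nodes: int
    mapping_report: locus_mod.MappingReport
    config: PipelineConfig
    chrom_order: list[str] = field(default_factory=list)

    @property
    def hc_loci(self) -> list[locus_mod.InsertionLocus]:
        return [lo for lo in self.loci if lo.confidence == "HC"]

    def insertion_tsv(self) -> str:
        return locus_mod.loci_to_tsv(self.loci)

    def insertion_bed(self) -> str:
        return locus_mod.loci_to_bed(self.loci)

    def summary_tsv(self) -> str:
        lines = ["metric\tvalue"]
        lines.append(f"pairs_in\t{self.qc_report.pairs_in}")
        lines.append(f"pairs_removed_qc\t{self.qc_report.pairs_removed}")
        lines.append(f"pairs_kept\t{self.qc_report.pairs_kept}")
        for t in (1, 2, 3, 4, 5):
            lines.append(f"type{t}_pairs\t{self.pair_type_counts.get(t, 0)}")
        lines.append(f"hybrid_reads\t{self.n_hybrids}")
        lines.append(f"contig_nodes\t{self.n_nodes}")
        lines.append(f"evidence_mapped\t{self.mapping_report.mapped}")
        lines.append(f"evidence_unmapped\t{self.mapping_report.unmapped}")
        lines.append(f"evidence_multimapped\t{self.mapping_report.multimapped}")
        lines.append(f"loci_total\t{len(self.loci)}")
        lines.append(f"loci_hc\t{len(self.hc_loci)}")
        return "\n".join(lines) + "\n"


def _kmer_at(codes: np.ndarray, offset: int, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed k-mers at one fixed offset of every row; (values, valid)."""
    window = codes[:, offset : offset + k]
    valid = ~np.any(window == 4, axis=1)
    vals = np.zeros(len(codes), dtype=np.uint64)
    for j in range(k):
        vals = vals * np.uint64(4) + np.where(window[:, j] == 4, 0, window[:, j]).astype(np.uint64)
    return vals, valid


def _place_unique(
    seqs: list[str], index: align.KmerIndex
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anchor each same-length sequence at a unique genome position via exact
    seed k-mers at a few fixed offsets. Returns (placed, target_id, start)."""
    n = len(seqs)
    placed = np.zeros(n, dtype=bool)
    tids = np.full(n, -1, dtype=np.int32)
    starts = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return placed, tids, starts
    L = len(seqs[0])
    k = index.k
    if L < k:
        return placed, tids, starts
    offsets = sorted({0, (L - k) // 2, L - k})
    chunk = 200_000
    for lo_i in range(0, n, chunk):
        block = seqs[lo_i : lo_i + chunk]
        codes = align.encode("".join(block)).reshape(len(block), L)
        for off in offsets:
            vals, valid = _kmer_at(codes, off, k)
            lo, hi = index.lookup(vals)
            unique = (hi - lo == 1) & valid
            idx = np.nonzero(unique & ~placed[lo_i : lo_i + len(block)])[0]
            if len(idx) == 0:
                continue
            occ = lo[idx]
            tids[lo_i + idx] = index._tids[occ]
            starts[lo_i + idx] = index._offsets[occ] - off
            placed[lo_i + idx] = True
    ok = placed & (starts >= 0)
    placed &= ok
    return placed, tids, starts


def _spanning_counts(
    loci: Sequence[locus_mod.InsertionLocus],
    type2_pairs: list[core_io.ReadPair],
    index: align.KmerIndex,
    read_length_hint: int | None = None,
) -> dict[int, int]:
    """Spanning-fragment count per locus index from type 2 pairs.

    A fragment spans a breakpoint when its mates place uniquely on the same
    chromosome on opposite sides of the breakpoint with the breakpoint
    strictly inside the implied fragment."""
    if not loci or not type2_pairs:
        return {i: 0 for i in range(len(loci))}
    lens = {len(p.read1.sequence) for p in type2_pairs} | {
        len(p.read2.sequence) for p in type2_pairs
    }
    if len(lens) != 1:
        # mixed read lengths: fall back to the per-pair op on every pair
        placed_pairs = []
        for p in type2_pairs:
            pp = _place_pair_slow(p, index)
            if pp is not None:
                placed_pairs.append(pp)
        return {
            i: locus_mod.count_spanning_pairs(lo.chrom, lo.position, placed_pairs)
            for i, lo in enumerate(loci)
        }
    (L,) = lens
    seq1 = [p.read1.sequence for p in type2_pairs]
    seq2rc = [align.reverse_complement(p.read2.sequence) for p in type2_pairs]
    placed1, tid1, pos1 = _place_unique(seq1, index)
    placed2, tid2, pos2 = _place_unique(seq2rc, index)
    ok = placed1 & placed2 & (tid1 == tid2)
    frag = pos2 + L - pos1
    ok &= (frag >= 2 * L) & (frag <= 20 * L)  # orientation/insert sanity
    counts: dict[int, int] = {}
    tid_of = {name: i for i, name in enumerate(index.target_names)}
    for i, lo in enumerate(loci):
        t = tid_of.get(lo.chrom)
        if t is None:
            counts[i] = 0
            continue
        b = lo.position
        sel = (
            ok
            & (tid1 == t)
            & (pos1 + L <= b)  # left mate (1-based end pos1+L) entirely at or left of b
            & (pos2 + 1 >= b)  # right mate (1-based start pos2+1) at or right of b
            & (pos1 + 1 < b)
            & (pos2 + L > b)
        )
        counts[i] = int(np.count_nonzero(sel))
    return counts


def _place_pair_slow(pair: core_io.ReadPair, index: align.KmerIndex):
    hits1 = align.seeded_local_align(pair.read1.sequence, index, min_score=40)
    hits2 = align.seeded_local_align(pair.read2.sequence, index, min_score=40)
    if len(hits1) != 1 or len(hits2) != 1:
        return None
    h1, h2 = hits1[0], hits2[0]
    if h1.target_id != h2.target_id:
        return None
    iv1 = (h1.target_start + 1, h1.target_end)
    iv2 = (h2.target_start + 1, h2.target_end)
    left, right = (iv1, iv2) if iv1[0] <= iv2[0] else (iv2, iv1)
    return locus_mod.PlacedPair(
        chrom=h1.target_id,
        left_start=left[0], left_end=left[1],
        right_start=right[0], right_end=right[1],
    )


def detect(
    pairs: Sequence[core_io.ReadPair],
    genome: Sequence[tuple[str, str]],
    element: core_io.TransposonReference,
    config: PipelineConfig | None = None,
) -> DetectionResult:
    """Run the full detection workflow on in-memory inputs."""
    config = (config or PipelineConfig()).validate()
    scoring = align.Scoring(config.match, config.mismatch, config.gap)

    kept, qc_report = core_io.qc_filter_pairs(
        pairs, config.low_quality_threshold, config.max_low_fraction
    )
    logger.info("QC: %d pairs in, %d kept, %d removed",
                qc_report.pairs_in, qc_report.pairs_kept, qc_report.pairs_removed)

    classified = classify.classify_pairs(
        kept, element,
        min_element_match=config.min_element_match,
        min_identity=config.min_identity,
        min_genomic_tail=config.min_genomic_tail,
        full_match_slack=config.full_match_slack,
        terminal_k=config.terminal_k,
    )
    type_counts = classify.pair_type_counts(classified)
    logger.info("pair types: %s", type_counts)

    hybrids = classify.collect_hybrids(classified)
    rescue_groups = assemble.collect_rescue_reads(classified)
    nodes = assemble.assemble_rescue_groups(
        rescue_groups, k=config.assembly_k, min_kmer_count=config.min_kmer_count
    )
    logger.info("%d hybrid reads, %d rescue reads (LE=%d RE=%d), %d nodes",
                len(hybrids), sum(len(g) for g in rescue_groups.values()),
                len(rescue_groups.get("LE", [])), len(rescue_groups.get("RE", [])),
                len(nodes))

    genome_index = align.build_kmer_index(list(genome), k=config.genome_k)
    evidence, mapping_report = locus_mod.map_evidence(
        hybrids, nodes, genome_index,
        min_identity=config.min_map_identity,
        min_mapped_len=config.min_mapped_len,
        min_coverage=config.min_map_coverage,
        scoring=scoring,
    )
    logger.info("evidence: %d mapped, %d unmapped, %d multimapped",
                mapping_report.mapped, mapping_report.unmapped, mapping_report.multimapped)

    hybrid_hits = [e for e in evidence if e.evidence_kind != "node"]
    node_hits = [e for e in evidence if e.evidence_kind == "node"]
    clusters = locus_mod.cluster_evidence(hybrid_hits, window=config.cluster_window)
    clusters = locus_mod.attach_nodes(
        clusters, node_hits,
        max_dist=config.node_attach_dist, window=config.cluster_window,
    )
    loci = [locus_mod.assign_confidence(cl, config.hc_min_support) for cl in clusters]

    type2 = [cp.pair for cp in classified if cp.pair_type == 2]
    spans = _spanning_counts(loci, type2, genome_index)
    for i, lo in enumerate(loci):
        lo.spanning_pairs = spans.get(i, 0)
        if lo.spanning_pairs == 0 and lo.support.total >= config.hc_min_support:
            lo.zygosity = "homozygous"
        elif lo.spanning_pairs >= config.min_span:
            lo.zygosity = "heterozygous"
        else:
            lo.zygosity = "undetermined"

    chrom_order = [name for name, _ in genome]
    loci = locus_mod.number_loci(loci, chrom_order)
    logger.info("%d loci (%d HC)", len(loci), sum(lo.confidence == "HC" for lo in loci))
    return DetectionResult(
        loci=loci,
        qc_report=qc_report,
        pair_type_counts=type_counts,
        n_hybrids=len(hybrids),
        n_nodes=len(nodes),
        mapping_report=mapping_report,
        config=config,
        chrom_order=chrom_order,
    )


def detect_from_files(
    reads1,
    reads2,
    genome_fasta,
    element_fasta,
    config: PipelineConfig | None = None,
    output_dir=None,
) -> DetectionResult:
    """File-based entry point; optionally writes the output tables."""
    config = (config or PipelineConfig()).validate()
    genome = core_io.read_fasta(genome_fasta)
    element = core_io.load_transposon(
        element_fasta, ltr_length=config.ltr_length, terminal_length=config.terminal_length
    )
    pairs = list(core_io.read_fastq_pairs(reads1, reads2))
    result = detect(pairs, genome, element, config)
    if output_dir is not None:
        write_outputs(result, output_dir)
    return result


def write_outputs(result: DetectionResult, output_dir) -> None:
    os.makedirs(output_dir, exist_ok=True)
    out = lambda name: os.path.join(output_dir, name)  # noqa: E731
    with open(out("insertions.tsv"), "w") as fh:
        fh.write(result.insertion_tsv())
    with open(out("insertions.bed"), "w") as fh:
        fh.write(result.insertion_bed())
    with open(out("summary.tsv"), "w") as fh:
        fh.write(result.summary_tsv())
    with open(out("qc.tsv"), "w") as fh:
        fh.write(result.qc_report.to_tsv())
    with open(out("config.txt"), "w") as fh:
        fh.write(f"# config digest: {result.config.digest()}\n")
        fh.write(result.config.to_text())
    with open(out("reports.json"), "w") as fh:
        json.dump(
            {
                "qc": vars(result.qc_report) if not hasattr(result.qc_report, "__slots__")
                else {s: getattr(result.qc_report, s) for s in result.qc_report.__slots__},
                "pair_types": result.pair_type_counts,
                "mapping": {
                    s: getattr(result.mapping_report, s)
                    for s in result.mapping_report.__slots__
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
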