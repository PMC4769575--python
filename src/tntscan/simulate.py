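"""Synthetic mutant-genome and paired-end read simulator.

The generator emulates the sequencing design the detection pipeline was
built for: a host genome carrying planted copies of a ~5.3 kb transposon
with identical 610 bp terminal repeats, sequenced as 90 bp paired-end reads
from ~500 bp fragments at ~40X with a small substitution error rate.
Insertions create a short target-site duplication (default 5 bp, typical of
copia-family LTR elements) and may be homozygous (both haplotypes) or
heterozygous (one haplotype). Every planted insertion is recorded in a
ground-truth table so recovery can be scored exactly.

Defaults (the simulated study conditions): 2 chromosomes x 500 kb at GC 0.5,
20 insertions, TSD 5 bp, 90 bp reads, 500 +/- 50 bp inserts, 40X coverage,
0.1% substitution error. Fragment starts are uniform (no GC bias) and the
error model is substitution-only with flat qualities (Q35, errored bases
Q15); these simplifications are deliberate — see the methods note.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import TransposonReference
from .locus import InsertionLocus

DEFAULT_N_CHROMS = 2
DEFAULT_CHROM_LENGTH = 500_000
DEFAULT_GC = 0.5
DEFAULT_N_INSERTIONS = 20
DEFAULT_TSD = 5
DEFAULT_READ_LENGTH = 90
DEFAULT_INSERT_MEAN = 500
DEFAULT_INSERT_SD = 50
DEFAULT_COVERAGE = 40.0
DEFAULT_ERROR_RATE = 0.001

# Fixed seed *sequence* for the packaged element: list-seeding draws from a
# different stream than any plain-integer user seed, so a simulated genome
# can never accidentally replay the element's bases.
_ELEMENT_SEED = (20160525, 5300, 610)
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC[_a] = _b


@dataclass(slots=True)
class InsertionTruth:
    chrom: str
    position: int  # 1-based coordinate of the last reference base before the element
    orientation: str  # + or -
    zygosity: str  # hom or het
    tsd_length: int


@dataclass
class SimulationTruth:
    """Ground truth for one simulated dataset.

    ``hap_junctions`` maps each haplotype sequence name to the 0-based
    boundary offsets (left junction, right junction, insertion index) of
    every element copy it carries, enabling exact per-read junction checks.
    """

    insertions: list[InsertionTruth]
    read_params: dict
    seed: int
    genome: list[tuple[str, str]] = field(default_factory=list, repr=False)
    haplotypes: list[tuple[str, str]] = field(default_factory=list, repr=False)
    hap_junctions: dict[str, list[tuple[int, int, int]]] = field(default_factory=dict)
    genome_files: list[str] = field(default_factory=list)

    def truth_tsv(self) -> str:
        lines = ["chrom\tposition\torientation\tzygosity\ttsd_length"]
        for t in self.insertions:
            lines.append(f"{t.chrom}\t{t.position}\t{t.orientation}\t{t.zygosity}\t{t.tsd_length}")
        return "\n".join(lines) + "\n"


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def synthetic_element(
    length: int = 5300, ltr_length: int = 610, terminal_length: int = 90
) -> TransposonReference:
    """The packaged synthetic transposon: ``length`` bp with two identical
    ``ltr_length`` bp terminal repeats, generated from a fixed seed so every
    installation ships the same element. Users may load a real element FASTA
    instead via :func:`tntscan.core_io.load_transposon`."""
    rng = np.random.default_rng(list(_ELEMENT_SEED))
    ltr = _random_dna(rng, ltr_length, 0.5)
    interior = _random_dna(rng, length - 2 * ltr_length, 0.5)
    return TransposonReference(
        name="Tnt1-like-synthetic",
        sequence=ltr + interior + ltr,
        ltr_length=ltr_length,
        terminal_length=terminal_length,
    )


def generate_genome(
    n_chroms: int = DEFAULT_N_CHROMS,
    length_per_chrom: int = DEFAULT_CHROM_LENGTH,
    gc: float = DEFAULT_GC,
    seed: int = 1,
) -> list[tuple[str, str]]:
    """I.i.d. random host genome at the stated GC; chr1..chrN; deterministic
    for a fixed seed."""
    if length_per_chrom < 10_000:
        raise ValueError("length_per_chrom must be >= 10 kb")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    return [(f"chr{i + 1}", _random_dna(rng, length_per_chrom, gc)) for i in range(n_chroms)]


def _reverse_complement_str(seq: str) -> str:
    return _RC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)][::-1].tobytes().decode("ascii")


def plant_insertions(
    genome: Sequence[tuple[str, str]],
    element: TransposonReference,
    n: int = DEFAULT_N_INSERTIONS,
    zygosity_mix: float = 0.0,
    tsd_length: int = DEFAULT_TSD,
    seed: int = 1,
    insert_mean: int = DEFAULT_INSERT_MEAN,
    min_separation: int | None = None,
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Plant ``n`` element copies at random positions and build the two
    haplotypes.

    ``zygosity_mix`` is the fraction of heterozygous insertions (rounded to a
    count); heterozygous copies go on haplotype A only. Sites keep at least
    2 x ``insert_mean`` from chromosome ends and (by default) 4 x
    ``insert_mean`` from each other so loci are independently resolvable.
    At each site the ``tsd_length`` target bases immediately left of the
    insertion point are duplicated to flank the element:
    ``genome[:p] + element + genome[p-tsd:p] + genome[p:]``.
    """
    if n < 1:
        raise ValueError("need n >= 1 insertions")
    if min_separation is None:
        min_separation = 4 * insert_mean
    rng = np.random.default_rng(seed)
    margin = 2 * insert_mean
    chrom_names = [name for name, _ in genome]
    chrom_lens = {name: len(seq) for name, seq in genome}
    usable = {c: chrom_lens[c] - 2 * margin for c in chrom_names}
    if any(u <= 0 for u in usable.values()) or sum(usable.values()) < n * min_separation * 2:
        raise ValueError(
            "cannot place insertions under the spacing constraints; use a longer genome"
        )
    sites: dict[str, list[int]] = {c: [] for c in chrom_names}
    weights = np.array([usable[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    placed = 0
    attempts = 0
    while placed < n:
        attempts += 1
        if attempts > 10_000 * n:
            raise ValueError("cannot place insertions under the spacing constraints")
        c = chrom_names[int(rng.choice(len(chrom_names), p=weights))]
        p = int(rng.integers(margin, chrom_lens[c] - margin))
        if all(abs(p - q) >= min_separation for q in sites[c]):
            sites[c].append(p)
            placed += 1
    insertions: list[InsertionTruth] = []
    for c in chrom_names:
        for p in sorted(sites[c]):
            insertions.append(InsertionTruth(chrom=c, position=p, orientation="+",
                                             zygosity="hom", tsd_length=tsd_length))
    orient = rng.random(n) < 0.5
    for t, flip in zip(insertions, orient):
        t.orientation = "-" if flip else "+"
    n_het = int(round(n * zygosity_mix))
    het_idx = rng.choice(n, size=n_het, replace=False) if n_het else np.array([], dtype=int)
    for i in het_idx:
        insertions[i].zygosity = "het"

    elem_fwd = element.sequence
    elem_rev = _reverse_complement_str(elem_fwd)
    haplotypes: list[tuple[str, str]] = []
    hap_junctions: dict[str, list[tuple[int, int, int]]] = {}
    for hap in ("A", "B"):
        for name, seq in genome:
            hap_name = f"{name}_hap{hap}"
            chosen = [
                (i, t) for i, t in enumerate(insertions)
                if t.chrom == name and (t.zygosity == "hom" or hap == "A")
            ]
            chosen.sort(key=lambda it: it[1].position)
            pieces: list[str] = []
            junctions: list[tuple[int, int, int]] = []
            prev = 0
            offset = 0
            for i, t in chosen:
                p = t.position
                elem = elem_fwd if t.orientation == "+" else elem_rev
                pieces.append(seq[prev:p])
                offset += p - prev
                left_jcn = offset
                pieces.append(elem)
                offset += len(elem)
                right_jcn = offset
                pieces.append(seq[p - t.tsd_length : p])
                offset += t.tsd_length
                junctions.append((left_jcn, right_jcn, i))
                prev = p
            pieces.append(seq[prev:])
            haplotypes.append((hap_name, "".join(pieces)))
            hap_junctions[hap_name] = junctions
    truth = SimulationTruth(
        insertions=insertions,
        read_params={},
        seed=seed,
        genome=list(genome),
        haplotypes=haplotypes,
        hap_junctions=hap_junctions,
    )
    return haplotypes, truth


def _open_out(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "wb", compresslevel=1)
    return open(path, "wb")


def simulate_pairs(
    haplotypes: Sequence[tuple[str, str]],
    out1,
    out2,
    coverage: float = DEFAULT_COVERAGE,
    read_length: int = DEFAULT_READ_LENGTH,
    insert_mean: int = DEFAULT_INSERT_MEAN,
    insert_sd: int = DEFAULT_INSERT_SD,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 1,
    return_origins: bool = False,
):
    """Draw fragments uniformly from the haplotypes and write the mate FASTQ
    files (gzipped when the path ends in .gz).

    Read 1 is the fragment's 5' end, read 2 the reverse complement of its 3'
    end. Fragment lengths are Normal(insert_mean, insert_sd) truncated at
    2 x read_length. Total read bases ~= coverage x haploid genome length
    (haploid = total haplotype length / 2). Substitution errors are i.i.d.
    at ``error_rate``; qualities are Q35 with errored bases at Q15.
    Deterministic per seed. With ``return_origins`` also returns per-fragment
    (haplotype index, start, length) arrays for truth-aware checks.
    """
    if insert_mean <= 2 * read_length:
        raise ValueError("insert_mean must exceed 2 x read_length")
    rng = np.random.default_rng(seed)
    names = [name for name, _ in haplotypes]
    seqs = [np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, seq in haplotypes]
    lens = np.array([len(s) for s in seqs], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    concat = np.concatenate(seqs)
    haploid_len = float(lens.sum()) / 2.0
    n_frags = int(round(coverage * haploid_len / (2 * read_length)))

    frag_len = rng.normal(insert_mean, insert_sd, size=n_frags)
    frag_len = np.maximum(np.rint(frag_len).astype(np.int64), 2 * read_length)
    hap_idx = rng.choice(len(seqs), size=n_frags, p=lens / lens.sum())
    span = lens[hap_idx] - frag_len
    span = np.maximum(span, 0)
    start = np.floor(rng.random(n_frags) * (span + 1)).astype(np.int64)
    gstart = offsets[hap_idx] + start

    idx = np.arange(read_length)
    r1 = concat[gstart[:, None] + idx]
    r2 = _RC[concat[(gstart + frag_len - read_length)[:, None] + idx]][:, ::-1]

    q_hi, q_lo = 33 + 35, 33 + 15
    fh1, fh2 = _open_out(out1), _open_out(out2)
    chunk = 65_536
    try:
        for lo in range(0, n_frags, chunk):
            hi = min(lo + chunk, n_frags)
            for mate, mat, fh in ((1, r1[lo:hi], fh1), (2, r2[lo:hi], fh2)):
                block = np.ascontiguousarray(mat)
                if error_rate > 0:
                    err = rng.random(block.shape) < error_rate
                    n_err = int(err.sum())
                    if n_err:
                        shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
                        codes = np.zeros(256, dtype=np.uint8)
                        codes[_BASES] = np.arange(4)
                        new = (codes[block[err]] + shift) % 4
                        block[err] = _BASES[new]
                else:
                    err = np.zeros(block.shape, dtype=bool)
                qual = np.full(block.shape, q_hi, dtype=np.uint8)
                qual[err] = q_lo
                out_parts = []
                for row in range(block.shape[0]):
                    i = lo + row
                    out_parts.append(
                        b"@frag%07d/%d\n%s\n+\n%s\n"
                        % (i, mate, block[row].tobytes(), qual[row].tobytes())
                    )
                fh.write(b"".join(out_parts))
    finally:
        fh1.close()
        fh2.close()
    params = dict(
        read_length=read_length, insert_mean=insert_mean, insert_sd=insert_sd,
        coverage=coverage, error_rate=error_rate, n_fragments=n_frags,
        haplotype_names=names,
    )
    if return_origins:
        return str(out1), str(out2), params, (hap_idx, start, frag_len)
    return str(out1), str(out2), params


def evaluate_recovery(
    called: Sequence[InsertionLocus],
    truth: SimulationTruth,
    tolerance: int = 10,
) -> dict:
    """Score called HC loci against planted insertions.

    A called HC locus is a true positive when it lies within ``tolerance``
    bp of a planted insertion on the same chromosome, matched one-to-one
    greedily by distance. Also reports the distance from every HC locus to
    the nearest planted insertion (unbounded), for precision auditing.
    """
    hc = [lo for lo in called if lo.confidence == "HC"]
    pairs = []
    for ti, t in enumerate(truth.insertions):
        for ci, lo in enumerate(hc):
            if lo.chrom == t.chrom and abs(lo.position - t.position) <= tolerance:
                pairs.append((abs(lo.position - t.position), ti, ci))
    pairs.sort()
    matched_truth: set[int] = set()
    matched_called: set[int] = set()
    offsets = []
    for dist, ti, ci in pairs:
        if ti in matched_truth or ci in matched_called:
            continue
        matched_truth.add(ti)
        matched_called.add(ci)
        offsets.append(dist)
    nearest = []
    for lo in hc:
        dists = [
            abs(lo.position - t.position) for t in truth.insertions if t.chrom == lo.chrom
        ]
        nearest.append(min(dists) if dists else float("inf"))
    n_truth = len(truth.insertions)
    return {
        "n_truth": n_truth,
        "n_hc_called": len(hc),
        "n_matched": len(matched_truth),
        "recall": len(matched_truth) / n_truth if n_truth else float("nan"),
        "precision": len(matched_called) / len(hc) if hc else float("nan"),
        "mean_abs_offset": float(np.mean(offsets)) if offsets else float("nan"),
        "max_hc_distance_to_truth": max(nearest) if nearest else float("nan"),
        "support_per_matched_locus": sorted(
            hc[ci].support.total for ci in matched_called
        ),
    }
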