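"""Sequence I/O, read quality control and transposon terminal extraction.

FASTQ is read and written as strict 4-line records with Phred+33 qualities
(the only encoding accepted; anything else is rejected rather than guessed).
FASTA parsing goes through Bio.SeqIO with names taken as the first
whitespace token of the header and sequences uppercased.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO


class FastqParseError(ValueError):
    """Malformed FASTQ record; message names the offending line number."""


class FastaParseError(ValueError):
    pass


@dataclass(slots=True)
class SequencingRead:
    """One sequencing read: id, bases over {A,C,G,T,N}, Phred+33 qualities."""

    read_id: str
    sequence: str
    qual: str  # Phred+33 encoded, same length as sequence
    mate: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qual):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qual)}"
            )
        if self.mate not in (1, 2):
            raise ValueError(f"read {self.read_id!r}: mate must be 1 or 2")

    @property
    def qualities(self) -> list[int]:
        """Phred scores as integers (Phred+33 decoded)."""
        return [ord(c) - 33 for c in self.qual]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(slots=True)
class ReadPair:
    """Two mated reads from one DNA fragment; the unit of classification."""

    pair_id: str
    read1: SequencingRead
    read2: SequencingRead

    def __post_init__(self) -> None:
        if self.read1.mate != 1 or self.read2.mate != 2:
            raise ValueError(f"pair {self.pair_id!r}: read1/read2 mate flags wrong")


@dataclass
class TransposonReference:
    """A transposon element with its terminal baits.

    The element carries two identical long terminal repeats (LTRs); the first
    ``terminal_length`` bases (left end, LE) and last ``terminal_length``
    bases (right end, RE) serve as classification baits for junction reads.
    """

    name: str
    sequence: str
    ltr_length: int = 610
    terminal_length: int = 90
    left_terminal: str = field(init=False)
    right_terminal: str = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not (0 < self.terminal_length <= self.ltr_length <= n // 2):
            raise ValueError(
                f"element {self.name!r}: need 0 < terminal_length "
                f"({self.terminal_length}) <= ltr_length ({self.ltr_length}) "
                f"<= element length/2 ({n // 2})"
            )
        self.left_terminal = self.sequence[: self.terminal_length]
        self.right_terminal = self.sequence[n - self.terminal_length :]


@dataclass(slots=True)
class QcReport:
    pairs_in: int = 0
    pairs_removed: int = 0
    pairs_kept: int = 0

    def to_tsv(self) -> str:
        return (
            "pairs_in\tpairs_removed\tpairs_kept\n"
            f"{self.pairs_in}\t{self.pairs_removed}\t{self.pairs_kept}\n"
        )


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


_VALID_SEQ = frozenset("ACGTN")


def read_fastq(path, mate: int = 1) -> Iterator[SequencingRead]:
    """Yield reads from a 4-line-record Phred+33 FASTQ file, in file order.

    Raises :class:`FastqParseError` naming the line number on malformed
    records (missing '@'/'+' markers, sequence/quality length mismatch,
    qualities outside the Phred+33 printable range).
    """
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FastqParseError(f"line {lineno}: expected '@' header, got {header[:30]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not plus:
                raise FastqParseError(f"line {lineno + 2}: truncated record (missing '+' line)")
            if not plus.startswith("+"):
                raise FastqParseError(f"line {lineno + 2}: expected '+' separator, got {plus[:30]!r}")
            if len(qual) != len(seq):
                raise FastqParseError(
                    f"line {lineno + 3}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            seq = seq.upper()
            if not set(seq) <= _VALID_SEQ:
                bad = sorted(set(seq) - _VALID_SEQ)
                raise FastqParseError(f"line {lineno + 1}: invalid sequence characters {bad}")
            if qual and (min(qual) < "!" or max(qual) > "~"):
                raise FastqParseError(f"line {lineno + 3}: quality characters outside Phred+33 range")
            lineno += 3
            yield SequencingRead(read_id=header[1:].split()[0] if header[1:] else "",
                                 sequence=seq, qual=qual, mate=mate)


def write_fastq(reads: Iterable[SequencingRead], path) -> None:
    """Write reads as 4-line Phred+33 records (round-trips `read_fastq`)."""
    with _open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qual}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (name, SEQUENCE) with enforced unique names."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        text = fh.read()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaParseError("sequence data before any '>' header")
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        name = rec.id
        if name in seen:
            raise FastaParseError(f"duplicate sequence name {name!r}")
        seen.add(name)
        records.append((name, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _pair_id_from(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[:-2]
    return read_id


def read_fastq_pairs(path1, path2) -> Iterator[ReadPair]:
    """Zip two FASTQ files into pairs, deriving pair ids from read names."""
    it1 = read_fastq(path1, mate=1)
    it2 = read_fastq(path2, mate=2)
    for r1, r2 in zip(it1, it2, strict=True):
        pid1, pid2 = _pair_id_from(r1.read_id), _pair_id_from(r2.read_id)
        if pid1 != pid2:
            raise FastqParseError(f"mate files out of sync: {r1.read_id!r} vs {r2.read_id!r}")
        yield ReadPair(pair_id=pid1, read1=r1, read2=r2)


def _low_quality_fraction(qual: str, threshold: int) -> float:
    if not qual:
        return 0.0
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33
    return float(np.mean(q < threshold))


def qc_filter_pairs(
    pairs: Iterable[ReadPair],
    low_quality_threshold: int = 20,
    max_low_fraction: float = 0.5,
) -> tuple[list[ReadPair], QcReport]:
    """Drop pairs in which either mate has strictly more than
    ``max_low_fraction`` of its bases below ``low_quality_threshold``.

    Removal is pair-level (both mates dropped together) so downstream
    pair-type logic never sees orphans. Adapter trimming is not performed;
    input reads are assumed adapter-free ("clean" reads).
    """
    if not 0.0 <= max_low_fraction <= 1.0:
        raise ValueError("max_low_fraction must be within [0, 1]")
    kept: list[ReadPair] = []
    report = QcReport()
    for pair in pairs:
        report.pairs_in += 1
        bad = (
            _low_quality_fraction(pair.read1.qual, low_quality_threshold) > max_low_fraction
            or _low_quality_fraction(pair.read2.qual, low_quality_threshold) > max_low_fraction
        )
        if bad:
            report.pairs_removed += 1
        else:
            report.pairs_kept += 1
            kept.append(pair)
    return kept, report


def qc_keep_mask(
    qual_matrix: np.ndarray, low_quality_threshold: int = 20, max_low_fraction: float = 0.5
) -> np.ndarray:
    """Vectorised QC: boolean keep-mask over a (n_pairs, 2, read_len) Phred
    array. Agrees with :func:`qc_filter_pairs` read-for-read."""
    low_frac = np.mean(qual_matrix < low_quality_threshold, axis=-1)
    return ~np.any(low_frac > max_low_fraction, axis=-1)


def load_transposon(path, ltr_length: int = 610, terminal_length: int = 90) -> TransposonReference:
    """Load the transposon element FASTA and extract terminal baits.

    Warns (does not fail) if the two LTR copies are not identical: real
    element clones can carry a handful of polymorphisms between repeats.
    """
    records = read_fasta(path)
    if len(records) != 1:
        raise ValueError(f"expected exactly one element sequence, found {len(records)}")
    name, seq = records[0]
    if len(seq) < 2 * ltr_length:
        raise ValueError(
            f"element {name!r} is {len(seq)} bp, shorter than 2 x ltr_length ({2 * ltr_length})"
        )
    tn = TransposonReference(
        name=name, sequence=seq, ltr_length=ltr_length, terminal_length=terminal_length
    )
    left_ltr = seq[:ltr_length]
    right_ltr = seq[len(seq) - ltr_length :]
    if left_ltr != right_ltr:
        warnings.warn(
            f"element {name!r}: left and right LTR copies are not identical",
            stacklevel=2,
        )
    return tn
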