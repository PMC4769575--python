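# Methods

`tntscan` locates insertion sites of an LTR retrotransposon (the ~5.3 kb
Tnt1-type element, with identical 610 bp long terminal repeats) in a host
genome from paired-end whole-genome sequencing reads. This note describes
the model and procedure, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## The detection model

A sequenced fragment can lie entirely in the host genome, entirely in an
element copy, or straddle an element–genome junction. Each 90 bp read is
labelled by alignment:

* **hybrid** — part of the read matches a 90 bp *terminal bait* (the first
  or last `terminal_length` bases of the element), the match is anchored at
  the element's outward edge (position 0 of the left end, or the last
  position of the right end), and the remainder is a genomic tail. The
  split point is the junction, recovered at base resolution.
* **element** — the read matches the full element end-to-end (within
  `full_match_slack` bases) at any position, on either strand. Because the
  two LTR copies are identical, a read inside an LTR cannot tell which copy
  it came from; it is still unambiguously *element*.
* **genomic** — everything else.

Anchoring at the outward edge is essential: the bait sequences recur inside
the element (each LTR carries both bait sequences at its own edges), so an
unanchored bait match does not imply a junction. A second guard arbitrates
every hybrid candidate against a full-element alignment: a read carrying a
sequencing error that lies wholly inside the element can otherwise satisfy
the split rule at the internal LTR–interior boundary, and such mis-splits
are systematic (they share one interior sequence and therefore pile up at
whatever reference position that sequence happens to half-match).

Mate labels combine into the five pair types: element–element (1),
genomic–genomic (2), hybrid–element (3), hybrid–genomic (4),
genomic–element (5). Two hybrids in one pair (one read per junction of a
short fragment) have no slot in the five-way taxonomy; the pair is recorded
as type 3 and both junction reads are kept as evidence. Types 3–5 are the
informative ones; type 2 pairs serve zygosity estimation.

## From reads to loci

1. **QC.** A pair is dropped when either mate has strictly more than
   `max_low_fraction` (default 0.5) of bases below Phred
   `low_quality_threshold` (default 20). Inputs are assumed adapter-free;
   dropping whole pairs keeps the pair-type logic free of orphans.
2. **Classification** as above, seeded by exact 11-mers against the element
   (both strands), scored by a linear-gap local aligner (match +1,
   mismatch −2, gap −3). A vectorised k-mer prefilter skips the genomic
   majority of reads.
3. **Assembly.** The genomic mates of type 4/5 pairs ("rescue reads") tile
   the flank next to each junction up to one insert length away. Grouped by
   the element end their mate implies (LE or RE; for element mates, by
   which half of the element the mate matched), they are assembled into
   unitigs of a de Bruijn graph (k = 21, k-mers kept at canonical count ≥ 2,
   dead-end tips shorter than 2k clipped, output deduplicated up to reverse
   complement and ordered lexicographically, so assembly is deterministic).
   Fragment geometry fixes which side of a contig faces the element: a
   genomic mate that is read 1 of its pair lies 5′ of the element on the
   reference strand, a read-2 mate 3′ of it.
4. **Mapping.** Hybrid genomic fragments and contigs are aligned to the
   reference by the same seed-and-extend aligner (13-mer seeds). A hit
   counts only if identity ≥ 0.9, aligned length ≥ 20 bp, and the alignment
   covers ≥ 80% of the evidence sequence — the coverage requirement rejects
   short chance matches of foreign sequence that the absolute floor would
   admit. Evidence with more than one equally-best location is discarded
   and reported as multi-mapping rather than placed arbitrarily. The
   breakpoint is the junction-proximal end of the mapped interval (for
   hybrids) or the element-facing end (for contigs).
5. **Clustering.** Hybrid breakpoints are clustered per chromosome by
   single linkage with a 100 bp window; left- and right-junction evidence
   of one element copy (offset only by the target-site duplication) merges
   into a single locus whose position is the lower median of member
   breakpoints. Contig evidence is then *attached* to the nearest cluster
   on the contig's element-facing side within `node_attach_dist` (default
   700 bp ≈ insert mean + 4 sd): rescue reads sit up to an insert length
   from the junction, so a contig's facing end systematically undershoots
   the breakpoint and would otherwise seed a side cluster of its own.
   Attachment adds support but never moves the position (hybrid breakpoints
   are base-accurate; contig ends are not). Contigs with no cluster in
   range form their own clusters, which rarely reach high confidence.
6. **Confidence and numbering.** A locus is high confidence (HC) with ≥ 3
   distinct supporting reads/contigs (each physical read or contig counted
   once), low confidence (LC) otherwise. Loci are sorted HC before LC, then
   by chromosome (caller-supplied order, unplaced scaffolds after the named
   chromosomes), then position, and numbered `Insertion-1`, `Insertion-2`, …
7. **Zygosity.** A type 2 fragment *spans* a breakpoint when its mates map
   uniquely to opposite sides with the breakpoint strictly inside the
   fragment. A homozygous insertion interrupts both haplotypes, so no
   fragment spans it: zero spanning fragments with junction support ≥ 3 ⇒
   homozygous; ≥ `min_span` (default 3) spanning fragments ⇒ heterozygous;
   anything else is undetermined. Mates are placed by unique exact seed
   k-mers at three fixed read offsets — exact for the uniquely-placeable
   reads that matter, and fast enough to scan every type 2 pair.

## Alignment

The production aligner finds exact k-mer seeds on both strands, groups them
by diagonal, widens each group to a window one query-length beyond the seed
span, and scores the window with an exact Smith–Waterman under the same
scoring scheme, so a reported hit's score *equals* the optimal local
alignment score of the query against that target region by construction.
Ties on score are kept (so multi-mapping ambiguity stays observable) and
broken deterministically (smallest query start, then target start) when one
hit must be chosen. Defaults: k = 13 for genome mapping, k = 11 against the
element — seeds must survive one error in a 90 bp read. The scheme has no
affine gaps or E-values; queries here are short and near-identical, where
linear gap costs are adequate.

## The simulator

The generator builds an i.i.d. random host genome (default 2 × 500 kb at GC
0.5), plants element copies at uniform positions (≥ 2 insert lengths from
chromosome ends and, by construction, ≥ 4 insert lengths apart so loci are
independently resolvable), duplicating `tsd_length` (default 5 bp, typical
of copia-family elements) target bases around each copy, in random
orientation; heterozygous copies go on one haplotype of two. Reads are 90 bp
pairs from Normal(500, 50) fragments drawn uniformly from the haplotypes at
40X, with i.i.d. substitution errors at 0.1% and flat qualities (Q35;
errored bases marked Q15). All randomness flows through one seeded
generator per operation; identical seeds give byte-identical FASTQ. The
packaged element is itself synthetic — 5300 bp with identical 610 bp LTRs
from a fixed seed — so no external sequence is required; a real element
FASTA can be supplied instead.

What this emulates: the read length, insert size, coverage and the junction
geometry (including the LTR ambiguity and TSD offset) that the classifier,
assembler and clusterer actually exercise. What it does not: indels and
quality-profile errors, GC and PCR bias, adapter read-through, duplicated
or repetitive host sequence, truncated or rearranged element copies, and
reference/sample polymorphism. Passing the recovery tests therefore shows
the method is correct under its own model, not that real-data recall would
be 100%: on real genomes, repeats and element-derived host sequence are the
main sources of multi-mapping losses and false joins, and they are exactly
the features the uniform-random genome lacks.

## Companion statistics

* Segregation: Pearson goodness-of-fit of wild-type:mutant counts against
  an expected ratio (default 3:1, the single-recessive-locus expectation),
  one degree of freedom, no continuity correction (the uncorrected
  statistic reproduces the published value for the 248:87 table; the
  variant printed for 258:70 is not reproducible under any standard form
  and is treated as an erratum, not a target).
* Fold coverage: clean bases / genome size, floored, with the raw ratio
  also reported (16.92 Gb over 384 Mb gives 44).
* FST dedup/overlap: two mapped sites within 100 bp (the same tolerance as
  locus clustering) count as one insertion; overlap uses nearest-first
  greedy one-to-one matching; unmapped records compare by exact sequence
  when sequences are given.

## Numerical and design choices

* Classification thresholds (`min_element_match` 15, `min_identity` 0.9,
  `min_genomic_tail` 20, `full_match_slack` 3) make both parts of a split
  90 bp read long enough to align reliably; they are artifact choices, as
  are the assembler's k/coverage cutoffs and the clustering window.
* Coordinates are 0-based half-open internally; reported positions are
  1-based (BED export converts back).
* "Low quality" is Phred < 20 — the filter's fraction (> 50%) is fixed by
  the sequencing-centre convention it reproduces, the threshold itself is a
  documented default.
* The whole pipeline is deterministic: no randomness after simulation, all
  ties broken by fixed keys, outputs byte-identical across reruns.
* Problem sizes in the test suite and acceptance script (1 Mb genomes, 20
  insertions, five replicate seeds; smaller genomes for the zygosity and
  soundness checks) are chosen so the full battery runs on a laptop-class
  machine while every pipeline branch is exercised at realistic coverage.

## Known limitations

Truncated or internally deleted element copies are not modelled (a hybrid
read anchored at a truncation boundary is missed); nested insertions and
insertions into repeats defeat unique placement by design (they surface in
the multi-mapping report instead of as calls); zygosity thresholds assume
even coverage; and the LC tier is reported but makes no quantitative claim
— single-read clusters are dominated by whatever systematic artefacts the
data carry.
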