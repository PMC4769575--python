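import numpy as np
import pytest

from tntscan import simulate as sim
from tntscan.align import reverse_complement
from tntscan.core_io import read_fastq
from tntscan.locus import InsertionLocus, SupportCounts


class TestGenerateGenome:
    def test_deterministic_for_fixed_seed(self):
        a = sim.generate_genome(2, 20_000, 0.5, seed=1)
        b = sim.generate_genome(2, 20_000, 0.5, seed=1)
        assert a == b
        c = sim.generate_genome(2, 20_000, 0.5, seed=2)
        assert a != c

    def test_chromosome_count_and_names(self):
        recs = sim.generate_genome(2, 15_000, 0.5, seed=1)
        assert [name for name, _ in recs] == ["chr1", "chr2"]

    def test_gc_content_concentrates(self):
        (_, seq), = sim.generate_genome(1, 100_000, 0.5, seed=9)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.49 <= gc <= 0.51  # binomial sd at 100 kb is ~0.0016

    def test_biased_gc(self):
        (_, seq), = sim.generate_genome(1, 100_000, 0.3, seed=9)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.29 <= gc <= 0.31

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_genome(1, 5000, 0.5, seed=1)

    def test_bad_gc_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_genome(1, 20_000, 1.5, seed=1)


class TestPlantInsertions:
    def test_single_homozygous_insertion_structure(self, element):
        genome = sim.generate_genome(1, 50_000, 0.5, seed=4)
        haps, truth = sim.plant_insertions(genome, element, n=1, tsd_length=5, seed=4)
        (t,) = truth.insertions
        name, g = genome[0]
        p = t.position
        elem = element.sequence if t.orientation == "+" else reverse_complement(element.sequence)
        expected = g[:p] + elem + g[p - 5 : p] + g[p:]
        by_name = dict(haps)
        assert by_name[f"{name}_hapA"] == expected
        assert by_name[f"{name}_hapB"] == expected  # homozygous: both altered
        assert len(expected) == len(g) + len(element.sequence) + 5

    def test_heterozygous_counts_exactly_realized(self, element):
        genome = sim.generate_genome(1, 400_000, 0.5, seed=5)
        haps, truth = sim.plant_insertions(genome, element, n=10, zygosity_mix=0.5, seed=5)
        zyg = [t.zygosity for t in truth.insertions]
        assert zyg.count("het") == 5 and zyg.count("hom") == 5
        by_name = dict(haps)
        # het copies only on haplotype A -> hapA strictly longer than hapB
        assert len(by_name["chr1_hapA"]) > len(by_name["chr1_hapB"])

    def test_minus_orientation_inserts_reverse_complement(self, element):
        genome = sim.generate_genome(1, 50_000, 0.5, seed=6)
        for seed in range(6, 12):
            haps, truth = sim.plant_insertions(genome, element, n=1, seed=seed)
            (t,) = truth.insertions
            if t.orientation == "-":
                hap = dict(haps)["chr1_hapA"]
                assert reverse_complement(element.sequence) in hap
                return
        pytest.fail("no minus-orientation insertion drawn across seeds")

    def test_spacing_invariants(self, element):
        genome = sim.generate_genome(2, 100_000, 0.5, seed=7)
        _, truth = sim.plant_insertions(genome, element, n=8, seed=7)
        for t in truth.insertions:
            assert 1000 <= t.position <= 100_000 - 1000
        per_chrom: dict[str, list[int]] = {}
        for t in truth.insertions:
            per_chrom.setdefault(t.chrom, []).append(t.position)
        for positions in per_chrom.values():
            ordered = sorted(positions)
            assert all(b - a >= 2000 for a, b in zip(ordered, ordered[1:]))

    def test_impossible_placement_raises(self, element):
        genome = sim.generate_genome(1, 12_000, 0.5, seed=8)
        with pytest.raises(ValueError, match="longer genome|spacing"):
            sim.plant_insertions(genome, element, n=50, seed=8)

    def test_truth_table_format(self, element):
        genome = sim.generate_genome(1, 50_000, 0.5, seed=4)
        _, truth = sim.plant_insertions(genome, element, n=1, seed=4)
        lines = truth.truth_tsv().strip().split("\n")
        assert lines[0] == "chrom\tposition\torientation\tzygosity\ttsd_length"
        assert len(lines) == 2


class TestSimulatePairs:
    def test_total_bases_match_requested_coverage(self, element, tmp_path):
        genome = sim.generate_genome(1, 50_000, 0.5, seed=4)
        haps, _ = sim.plant_insertions(genome, element, n=1, seed=4)
        r1, r2, params = sim.simulate_pairs(
            haps, tmp_path / "a1.fastq", tmp_path / "a2.fastq", coverage=20, seed=4
        )
        haploid = sum(len(s) for _, s in haps) / 2
        total_bases = params["n_fragments"] * 2 * 90
        assert abs(total_bases - 20 * haploid) / (20 * haploid) < 0.02

    def test_zero_error_reads_are_haplotype_substrings(self, tiny_sim):
        haps = tiny_sim["haplotypes"]
        joined = "\n".join(s for _, s in haps)
        for i, read in enumerate(read_fastq(tiny_sim["reads1"])):
            assert read.sequence in joined or reverse_complement(read.sequence) in joined
            if i >= 200:
                break

    def test_same_seed_byte_identical(self, element, tmp_path):
        genome = sim.generate_genome(1, 30_000, 0.5, seed=3)
        haps, _ = sim.plant_insertions(genome, element, n=1, seed=3)
        paths = []
        for tag in ("x", "y"):
            r1, r2, _ = sim.simulate_pairs(
                haps, tmp_path / f"{tag}1.fastq", tmp_path / f"{tag}2.fastq",
                coverage=5, seed=99,
            )
            paths.append((r1, r2))
        for a, b in zip(paths[0], paths[1]):
            assert open(a, "rb").read() == open(b, "rb").read()

    def test_fragment_length_distribution(self, tiny_sim):
        hap_idx, start, frag_len = tiny_sim["origins"]
        assert len(frag_len) >= 10_000
        assert abs(float(np.mean(frag_len)) - 500) / 500 < 0.02

    def test_insert_mean_must_exceed_reads(self, element, tmp_path):
        genome = sim.generate_genome(1, 30_000, 0.5, seed=3)
        haps, _ = sim.plant_insertions(genome, element, n=1, seed=3)
        with pytest.raises(ValueError):
            sim.simulate_pairs(haps, tmp_path / "b1.fq", tmp_path / "b2.fq",
                               insert_mean=150, read_length=90, seed=1)

    def test_error_rate_marks_qualities(self, element, tmp_path):
        genome = sim.generate_genome(1, 30_000, 0.5, seed=3)
        haps, _ = sim.plant_insertions(genome, element, n=1, seed=3)
        r1, _, _ = sim.simulate_pairs(
            haps, tmp_path / "e1.fastq", tmp_path / "e2.fastq",
            coverage=3, error_rate=0.01, seed=5,
        )
        joined = "\n".join(s for _, s in haps)
        n_err_marked = 0
        for read in read_fastq(r1):
            quals = np.array(read.qualities)
            if np.any(quals == 15):
                n_err_marked += 1
                assert read.sequence not in joined  # the marked base really changed
        assert n_err_marked > 0


def _hc(chrom, pos):
    return InsertionLocus(
        insertion_id="x", chrom=chrom, position=pos,
        support=SupportCounts(hybrid_LE=3), confidence="HC",
    )


class TestEvaluateRecovery:
    def _truth(self, element, positions):
        genome = sim.generate_genome(1, 200_000, 0.5, seed=10)
        _, truth = sim.plant_insertions(genome, element, n=len(positions), seed=10)
        for t, p in zip(truth.insertions, positions):
            t.position = p
        return truth

    def test_perfect_calls(self, element):
        truth = self._truth(element, [10_000, 50_000, 90_000])
        called = [_hc("chr1", p) for p in (10_000, 50_000, 90_000)]
        m = sim.evaluate_recovery(called, truth, tolerance=10)
        assert m["recall"] == 1.0 and m["precision"] == 1.0
        assert m["mean_abs_offset"] == 0.0

    def test_empty_calls(self, element):
        truth = self._truth(element, [10_000, 50_000, 90_000])
        m = sim.evaluate_recovery([], truth, tolerance=10)
        assert m["recall"] == 0.0

    def test_spurious_call_hurts_precision(self, element):
        truth = self._truth(element, [10_000, 50_000, 90_000])
        called = [_hc("chr1", p) for p in (10_000, 50_000, 90_000, 140_000)]
        m = sim.evaluate_recovery(called, truth, tolerance=10)
        assert m["precision"] < 1.0
        assert m["max_hc_distance_to_truth"] == 50_000

    def test_one_to_one_matching(self, element):
        truth = self._truth(element, [10_000, 50_000, 90_000])
        called = [_hc("chr1", 10_001), _hc("chr1", 10_002)]
        m = sim.evaluate_recovery(called, truth, tolerance=10)
        assert m["n_matched"] == 1 and m["precision"] == 0.5
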