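import numpy as np
import pytest

from tntscan import simulate as sim


@pytest.fixture(scope="session")
def element():
    """The packaged synthetic transposon (5300 bp, identical 610 bp LTRs)."""
    return sim.synthetic_element()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_genome():
    """One 100 kb random chromosome for mapping tests."""
    return sim.generate_genome(n_chroms=1, length_per_chrom=100_000, gc=0.5, seed=42)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory, element):
    """A small error-free simulated dataset shared by truth-aware tests:
    200 kb, 5 homozygous insertions, 40X, zero error rate."""
    out = tmp_path_factory.mktemp("tinysim")
    genome = sim.generate_genome(n_chroms=1, length_per_chrom=200_000, gc=0.5, seed=11)
    haps, truth = sim.plant_insertions(genome, element, n=5, zygosity_mix=0.0, seed=11)
    r1, r2, params, origins = sim.simulate_pairs(
        haps, out / "r1.fastq", out / "r2.fastq",
        coverage=40, error_rate=0.0, seed=11, return_origins=True,
    )
    return {
        "genome": genome, "haplotypes": haps, "truth": truth,
        "reads1": r1, "reads2": r2, "params": params, "origins": origins,
    }
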