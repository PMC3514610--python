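import numpy as np
import pytest

from tetrabin import calibration, simulate

# A reduced length grid keeps the shared fixture cheap; unit tests that need
# exact grid semantics build their own tables.
TINY_LENGTHS = (500, 1000, 2000, 5000, 10000, 20000, 50000)


@pytest.fixture(scope="session")
def tiny_genomes():
    # tg2 is long so tests can draw a bin anchor whose mean vector is a good
    # stand-in for the genome mean
    sizes = (400_000, 400_000, 1_200_000, 400_000, 400_000)
    return [simulate.make_genome(n, gc=gc, order=3, seed=1000 + i,
                                 genome_id=f"tg{i}")
            for i, (n, gc) in enumerate(zip(sizes, (0.40, 0.45, 0.50, 0.55, 0.60)))]


@pytest.fixture(scope="session")
def tiny_tables(tiny_genomes):
    return calibration.build_tables([(g.id, g.seq) for g in tiny_genomes],
                                    lengths=TINY_LENGTHS, n_per_length=100, seed=42)


@pytest.fixture(scope="session")
def small_community():
    return simulate.make_community(n_genomes=3, genome_length=500_000,
                                   n_contigs_per_genome=40,
                                   contig_length_range=(2000, 30000), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, n, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])
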