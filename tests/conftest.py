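import numpy as np
import pytest

from neomerkit import GenomeSequence, build_presence_set, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 5 kb random genome, big enough for realistic windows but small
    enough that k<=8 nullomers are abundant."""
    return simulate_genome(5000, seed=11)


@pytest.fixture(scope="session")
def small_pset(small_genome):
    return build_presence_set(small_genome, 8)


def naive_presence(genome: GenomeSequence, k: int) -> set:
    """Brute-force oracle: every N-free window and its reverse complement."""
    from neomerkit import reverse_complement

    present = set()
    for _name, seq in genome:
        for i in range(len(seq) - k + 1):
            w = seq[i:i + k]
            if set(w) <= set("ACGT"):
                present.add(w)
                present.add(reverse_complement(w))
    return present


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
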