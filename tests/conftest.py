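import numpy as np
import pytest

from cgrfractal import AbundanceProfile, ReadSet

# example 10-species community used in the worked diversity example:
# one species absent, strongly uneven abundances
EXAMPLE_ABUNDANCES = [
    0.016928832,
    0.30559462,
    0.120814049,
    0.0,
    0.07959993,
    0.00894306,
    0.03682631,
    0.37768779,
    0.00570905,
    0.04789635,
]


@pytest.fixture
def example_profile() -> AbundanceProfile:
    labels = [f"species_{i}" for i in range(10)]
    return AbundanceProfile(labels, np.array(EXAMPLE_ABUNDANCES))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230126)


def random_reads(rng, n_reads, length, alphabet="ACGT") -> ReadSet:
    letters = np.array(list(alphabet))
    return ReadSet.from_sequences(
        ["".join(rng.choice(letters, size=length)) for _ in range(n_reads)]
    )


@pytest.fixture
def uniform_reads(rng) -> ReadSet:
    return random_reads(rng, 50, 300)


@pytest.fixture
def fasta_file(tmp_path):
    p = tmp_path / "reads.fasta"
    p.write_text(">a\nACGT\n>b\nGGCC\n")
    return p
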