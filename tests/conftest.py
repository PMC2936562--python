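import numpy as np
import pytest

from subspecscan.alignment import GroupPartition, MultiStrainAlignment


@pytest.fixture
def tiny_alignment():
    """Four strains, 12 bp, with one fixed difference (site 4), one group-A
    polymorphism (site 7) and one N-containing column (site 10)."""
    seqs = {
        "a1": "ACGTACGTACGT",
        "a2": "ACGTACTTACGT",
        "b1": "ACGAACGTACGT",
        "b2": "ACGAACGTANGT",
    }
    return MultiStrainAlignment(seqs)


@pytest.fixture
def tiny_partition():
    return GroupPartition({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(rng, n=6, length=60, alphabet="ACGT"):
    """Unstructured random alignment helper used by several test modules."""
    letters = np.array(list(alphabet))
    return MultiStrainAlignment(
        {
            f"s{i}": "".join(rng.choice(letters, size=length))
            for i in range(n)
        }
    )
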