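import numpy as np
import pytest

from pirnakit.sequence_io import NEGATIVE, POSITIVE, SequenceRecord, SequenceSet

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160413)


@pytest.fixture
def toy_labeled_set(rng) -> SequenceSet:
    """40 + 40 labeled records, positives forced to start with TG."""
    records = []
    for i in range(40):
        records.append(
            SequenceRecord(f"p{i}", "TG" + random_dna(rng, 28), POSITIVE)
        )
    for i in range(40):
        records.append(SequenceRecord(f"n{i}", random_dna(rng, 30), NEGATIVE))
    return SequenceSet(records, source="toy")
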