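import numpy as np
import pytest

from rnagru.io_formats import PairingMap, RnaSequence, StructureRecord
from rnagru.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_records():
    """A small, seeded synthetic training set (lengths 20-30, 2:3 ratio)."""
    return generate_dataset(
        SyntheticConfig(count=10, length_min=20, length_max=30,
                        paired_fraction=0.4, pk_prob=0.3, seed=11)
    )


@pytest.fixture()
def hairpin_record():
    """GGGAAACCC with the nested stem (((...)))."""
    return StructureRecord(
        RnaSequence("hairpin", "GGGAAACCC"),
        PairingMap([9, 8, 7, 0, 0, 0, 3, 2, 1]),
    )


def random_pairing_map(n: int, rng: np.random.Generator, p_pair: float = 0.4) -> PairingMap:
    """Arbitrary valid pairing map (crossings allowed, no min-loop constraint)."""
    partner = np.zeros(n, dtype=np.int64)
    order = rng.permutation(n)
    for a in range(0, n - 1, 2):
        i, j = int(order[a]), int(order[a + 1])
        if rng.random() < p_pair and abs(i - j) > 1:
            partner[i] = j + 1
            partner[j] = i + 1
    return PairingMap(partner)
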