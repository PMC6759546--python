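import numpy as np
import pytest

from psekgcc import DnaRecord, SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def micro_record():
    """The hand-worked example: GGG front, CCC*** middle, *** rear after the
    (0.25, 0.75) split of a length-12 sequence."""
    return DnaRecord(id="micro", sequence="GGGCCCAAATTT")


def random_records(rng, n, lo=60, hi=200, gc=0.5):
    """Plain i.i.d. random DNA records (no class structure)."""
    records = []
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        records.append(
            DnaRecord(id=f"r{i}", sequence="".join(rng.choice(bases, L, p=p)))
        )
    return records


@pytest.fixture
def skew_dataset_small():
    """n=30+30 synthetic dataset with the default skew structure."""
    cfg = SyntheticConfig(n_pos=30, n_neg=30, length_range=(150, 400), seed=7)
    return generate_dataset(cfg)
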