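import numpy as np
import pytest

from magqc import RepliconTruth, generate_replicon
from magqc.core import GeneModel


@pytest.fixture(scope="session")
def skewed_replicon():
    """A 100 kb circular replicon with a strong bidirectional skew
    signature: ori at 0, ter at 50 kb, skew strength 0.8."""
    truth = RepliconTruth(
        length=100_000, ori_pos=0, ter_pos=50_000,
        skew_strength=0.8, gc_content=0.5, seed=1,
    )
    seq, truth = generate_replicon(truth)
    return seq, truth


@pytest.fixture(scope="session")
def neutral_replicon():
    """A 50 kb replicon with no skew bias (i.i.d. composition)."""
    truth = RepliconTruth(
        length=50_000, ori_pos=0, ter_pos=25_000,
        skew_strength=0.0, gc_content=0.45, seed=2,
    )
    seq, truth = generate_replicon(truth)
    return seq, truth


@pytest.fixture(scope="session")
def gc_donors():
    """Two 30 kb donors differing strongly in GC content (0.30 vs 0.70),
    the raw material for chimeric-contig tests."""
    low = generate_replicon(
        RepliconTruth(30_000, 0, 15_000, 0.0, 0.30, seed=3)
    )[0]
    high = generate_replicon(
        RepliconTruth(30_000, 0, 15_000, 0.0, 0.70, seed=4)
    )[0]
    return low, high


@pytest.fixture
def small_genes():
    """Thirty well-separated 900 bp genes on a 70 kb reference."""
    return [
        GeneModel(f"g{i:02d}", "ref", 1_000 + i * 2_000, 1_000 + i * 2_000 + 900)
        for i in range(30)
    ]


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return bases[rng.choice(4, size=length, p=probs)].tobytes().decode()
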