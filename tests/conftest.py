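import numpy as np
import pytest

from ahtpscreen import LabeledDataset, Peptide, SimConfig, generate_dataset
from ahtpscreen.peptide_io import NEGATIVE_LABEL, POSITIVE_LABEL


def pep(seq: str, pid: str = "p") -> Peptide:
    return Peptide(pid, seq)


@pytest.fixture
def ylyelr() -> Peptide:
    """A short scorpion-venom AHTP used as a hand-checkable reference."""
    return Peptide("ylyelr", "YLYELR")


@pytest.fixture
def small_dataset() -> LabeledDataset:
    pos = ["YLYELR", "AFPYYGHHLG", "LVLPGE", "IPPAYTK", "LIIPQH", "LIPPEH"]
    neg = ["AAKLGE", "GSDMEAK", "TTVNNAL", "DEGSSAK", "MKLSDE", "GGASDE"]
    recs = [(Peptide(f"pos{i}", s), POSITIVE_LABEL) for i, s in enumerate(pos)]
    recs += [(Peptide(f"neg{i}", s), NEGATIVE_LABEL) for i, s in enumerate(neg)]
    return LabeledDataset(recs)


@pytest.fixture(scope="session")
def sim_small():
    """A modest synthetic dataset shared across tests (fixed seed)."""
    data, log = generate_dataset(SimConfig(n_pos=150, n_neg=150, seed=7))
    return data


def random_peptides(n: int, seed: int, lo: int = 5, hi: int = 25) -> list[Peptide]:
    rng = np.random.default_rng(seed)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        out.append(Peptide(f"r{i}", "".join(rng.choice(aa, L))))
    return out
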