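import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import umamistack as us
from umamistack._tables import ALPHABET

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_peptide(rng: np.random.Generator, lo: int = 2, hi: int = 30) -> us.Peptide:
    L = int(rng.integers(lo, hi + 1))
    seq = "".join(rng.choice(list(ALPHABET), size=L))
    return us.Peptide(id=f"r{rng.integers(10**9)}", sequence=seq)


@pytest.fixture(scope="session")
def fixtures():
    return us.fixture_peptides()


@pytest.fixture(scope="session")
def random_peptides():
    """100 random valid peptides, lengths 2-30, fixed seed."""
    rng = np.random.default_rng(20240917)
    return [random_peptide(rng) for _ in range(100)]


def separable_dataset(n_per_class: int = 20, seed: int = 0, name: str = "separable"):
    """Positives over {E, D} only, negatives over {F, L} only: any
    composition-aware classifier can separate them perfectly."""
    rng = np.random.default_rng(seed)
    peptides, labels = [], []
    seen = set()
    for label, letters, tag in ((1, "ED", "p"), (0, "FL", "n")):
        made = 0
        while made < n_per_class:
            L = int(rng.integers(3, 21))
            seq = "".join(rng.choice(list(letters), size=L))
            if seq in seen:
                continue
            seen.add(seq)
            made += 1
            peptides.append(us.Peptide(f"{tag}{made}", seq))
            labels.append(label)
    return us.make_dataset(peptides, labels, name=name)


@pytest.fixture(scope="session")
def signal_dataset():
    """Small strongly-separated synthetic dataset for pipeline tests."""
    return us.generate_dataset(us.high_signal_config(n_pos=15, n_neg=15, seed=7))
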