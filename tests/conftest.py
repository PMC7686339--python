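import numpy as np
import pytest

from kcrpred.dataprep import NEGATIVE, POSITIVE, PeptideWindow, prepare_windows, undersample
from kcrpred.encoders import AMINO_ACIDS
from kcrpred.synthetic import GeneratorConfig, generate


@pytest.fixture
def uniform_k_window() -> PeptideWindow:
    """A degenerate all-lysine 31-mer."""
    return PeptideWindow("K" * 31, POSITIVE, "U1", 16)


@pytest.fixture
def alternating_window() -> PeptideWindow:
    """'AKAK...A': 16 alanines at even offsets, 15 lysines at odd offsets."""
    return PeptideWindow("AK" * 15 + "A", NEGATIVE, "U2", 16)


def random_window(rng: np.random.Generator, n: int = 15) -> PeptideWindow:
    chars = rng.choice(list(AMINO_ACIDS), size=2 * n + 1)
    chars[n] = "K"
    return PeptideWindow("".join(chars), POSITIVE if rng.random() < 0.5 else NEGATIVE, "R", n + 1)


@pytest.fixture
def random_windows():
    rng = np.random.default_rng(20240917)
    return [random_window(rng) for _ in range(50)]


@pytest.fixture(scope="session")
def signal_dataset():
    """Synthetic dataset with the default planted K/E flank enrichment."""
    return generate(GeneratorConfig(n_proteins=60, seed=11))


@pytest.fixture(scope="session")
def balanced_signal_windows(signal_dataset):
    windows, _ = prepare_windows(signal_dataset.proteins, cluster=False)
    return undersample(windows, seed=5)
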