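import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from nitropred.windowing import (
    BenchmarkDataset,
    NEGATIVE,
    POSITIVE,
    PeptideWindow,
)
from nitropred.windowing import AMINO_ACIDS


def win(residues: str, label: str = "unlabeled", **kw) -> PeptideWindow:
    """Build a PeptideWindow with the half-width inferred from the string."""
    return PeptideWindow(residues, len(residues) // 2, label=label, **kw)


def random_dataset(
    n_pos: int, n_neg: int, half_width: int, seed: int
) -> BenchmarkDataset:
    """Unstructured random benchmark (both classes pure background)."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))

    def make(n, label):
        out = []
        for _ in range(n):
            chars = rng.choice(aa, size=2 * half_width + 1)
            chars[half_width] = "Y"
            out.append(PeptideWindow("".join(chars), half_width, label=label))
        return out

    return BenchmarkDataset(make(n_pos, POSITIVE), make(n_neg, NEGATIVE), half_width)


@pytest.fixture
def toy_dataset() -> BenchmarkDataset:
    """The two-peptide-per-class dataset behind the worked similarity example."""
    return BenchmarkDataset(
        [win("AYC", POSITIVE), win("AYD", POSITIVE)],
        [win("GYG", NEGATIVE), win("GYG", NEGATIVE)],
        1,
    )
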