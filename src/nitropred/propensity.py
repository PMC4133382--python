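"""Numeric residue coding and position-specific propensity matrices.

Residues are coded 1..20 for the native amino acids in alphabetical order of
their one-letter codes and 21 for the dummy residue X, giving 21 * 21 = 441
possible ordered dipeptides.  A (2*l + 1)-mer window has 2*l dipeptide
subsites — the overlapping adjacent residue pairs read left to right — and a
position-specific dipeptide propensity (PSDP) matrix is the 441 x 2l table of
per-class occurrence frequencies of each dipeptide at each subsite.  A
window's 2l-dimensional feature vector toward a class is the row lookup of
its observed dipeptides in that class's matrix.

A single-residue variant (21 x 2l over the 2l non-center window positions)
serves as the baseline encoder that ignores pairwise coupling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nitropred.errors import ContractError, EstimationError
from nitropred.windowing import ALPHABET_SYMBOLS, PeptideWindow

#: symbol -> numeric code 1..21 (A=1 ... Y=20, X=21)
ALPHABET: dict[str, int] = {s: i + 1 for i, s in enumerate(ALPHABET_SYMBOLS)}

N_SYMBOLS = 21
N_DIPEPTIDES = N_SYMBOLS * N_SYMBOLS  # 441

DIPEPTIDE = "dipeptide"
SINGLE_RESIDUE = "single_residue"


def dipeptide_index(a: str, b: str) -> int:
    """Row-major 1-based index of the ordered dipeptide (a, b) in 1..441."""
    try:
        ca, cb = ALPHABET[a], ALPHABET[b]
    except KeyError as exc:
        raise ContractError(f"unknown residue symbol {exc.args[0]!r}") from exc
    return (ca - 1) * N_SYMBOLS + cb


def subsite_dipeptides(window: PeptideWindow) -> list[int]:
    """The 2l dipeptide indices of a window's overlapping adjacent pairs.

    Subsite j (1-based, j = 1..2l) is the ordered pair of window residues at
    0-based offsets (j - 1, j).
    """
    r = window.residues
    return [dipeptide_index(r[j], r[j + 1]) for j in range(2 * window.half_width)]


@dataclass
class PropensityMatrix:
    """Per-class occurrence-frequency table: rows are dipeptides (441) or
    single residues (21), columns the 2l subsites / non-center positions.

    Counts are kept alongside the sample count so that frequencies are exact
    rationals and leave-one-out updates can decrement rather than retrain.
    """

    counts: np.ndarray  # integer, shape (n_rows, 2l)
    sample_count: int
    half_width: int
    class_tag: str
    mode: str = DIPEPTIDE

    @property
    def values(self) -> np.ndarray:
        """Frequency table counts / sample_count; every column sums to 1."""
        return self.counts / self.sample_count

    def __post_init__(self) -> None:
        expect_rows = N_DIPEPTIDES if self.mode == DIPEPTIDE else N_SYMBOLS
        if self.counts.shape != (expect_rows, 2 * self.half_width):
            raise ContractError(
                f"propensity matrix shape {self.counts.shape} does not match "
                f"mode {self.mode!r} at half_width {self.half_width}"
            )


def encode_window(window: PeptideWindow, mode: str = DIPEPTIDE) -> np.ndarray:
    """0-based row indices of a window, one per subsite/column (length 2l)."""
    if mode == DIPEPTIDE:
        return np.asarray(subsite_dipeptides(window), dtype=np.int64) - 1
    if mode == SINGLE_RESIDUE:
        l = window.half_width
        non_center = window.residues[:l] + window.residues[l + 1 :]
        return np.asarray([ALPHABET[c] - 1 for c in non_center], dtype=np.int64)
    raise ContractError(f"unknown encoder mode {mode!r}")


def encode_windows(windows: list[PeptideWindow], mode: str = DIPEPTIDE) -> np.ndarray:
    """Stacked row-index matrix, shape (n_windows, 2l)."""
    return np.stack([encode_window(w, mode) for w in windows])


def counts_from_codes(codes: np.ndarray, n_rows: int) -> np.ndarray:
    """Occurrence counts per (row index, column) from a (n, 2l) code matrix."""
    n, width = codes.shape
    counts = np.zeros((n_rows, width), dtype=np.int64)
    for j in range(width):
        counts[:, j] = np.bincount(codes[:, j], minlength=n_rows)
    return counts


def _compute(
    windows: list[PeptideWindow], half_width: int, class_tag: str, mode: str
) -> PropensityMatrix:
    if not windows:
        raise EstimationError(
            f"cannot estimate a {class_tag} propensity matrix from zero peptides"
        )
    for w in windows:
        if w.half_width != half_width:
            raise ContractError(
                f"window half_width {w.half_width} != requested {half_width}"
            )
    codes = encode_windows(windows, mode)
    n_rows = N_DIPEPTIDES if mode == DIPEPTIDE else N_SYMBOLS
    counts = counts_from_codes(codes, n_rows)
    return PropensityMatrix(counts, len(windows), half_width, class_tag, mode)


def compute_psdp(
    windows: list[PeptideWindow], half_width: int, class_tag: str
) -> PropensityMatrix:
    """Estimate the 441 x 2l position-specific dipeptide propensity matrix.

    Entry (i, j) is the fraction of the input peptides whose subsite-j
    dipeptide has index i.  Raw occurrence frequencies, no smoothing: an
    unseen dipeptide scores exactly zero.
    """
    return _compute(windows, half_width, class_tag, DIPEPTIDE)


def compute_psap(
    windows: list[PeptideWindow], half_width: int, class_tag: str
) -> PropensityMatrix:
    """Single-residue baseline: 21 x 2l occurrence frequencies of each residue
    at each of the 2l non-center window positions."""
    return _compute(windows, half_width, class_tag, SINGLE_RESIDUE)


@dataclass(frozen=True)
class FeatureVector:
    """A window's 2l propensity lookups toward one class."""

    components: tuple[float, ...]
    class_tag: str


def feature_vector(window: PeptideWindow, matrix: PropensityMatrix) -> FeatureVector:
    """Component j is matrix entry (observed row at subsite j, subsite j)."""
    if window.half_width != matrix.half_width:
        raise ContractError(
            f"window half_width {window.half_width} != matrix {matrix.half_width}"
        )
    codes = encode_window(window, matrix.mode)
    vals = matrix.values[codes, np.arange(codes.size)]
    return FeatureVector(tuple(float(v) for v in vals), matrix.class_tag)
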