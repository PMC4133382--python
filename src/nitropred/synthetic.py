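"""Synthetic benchmark generator with plantable dipeptide signal.

Generates tyrosine-centered windows whose flanks are drawn from a background
amino-acid distribution (uniform over the 20 native residues by default; the
dummy X never appears, since padding is a windowing artifact, not a residue).
Positives additionally receive *planted* position-specific dipeptides: each
plant (subsite, dipeptide, probability) overwrites its two window positions
with the given probability, applied left to right so later plants win on
overlap.  This emulates the class contrast a real nitration benchmark shows
between the residue-pair composition of nitrated and non-nitrated flanks,
with a controllable effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Sequence

import numpy as np

from nitropred.errors import ContractError, DataError
from nitropred.propensity import ALPHABET, N_DIPEPTIDES, N_SYMBOLS
from nitropred.windowing import (
    AMINO_ACIDS,
    BenchmarkDataset,
    NEGATIVE,
    POSITIVE,
    PeptideWindow,
)

_SYMBOLS = list(ALPHABET)  # index = code - 1


def dipeptide_symbols(index: int) -> tuple[str, str]:
    """Inverse of the row-major dipeptide index (1..441) -> symbol pair."""
    if not 1 <= index <= N_DIPEPTIDES:
        raise ContractError(f"dipeptide index {index} out of 1..441")
    a, b = divmod(index - 1, N_SYMBOLS)
    return _SYMBOLS[a], _SYMBOLS[b]


@dataclass
class MotifSpec:
    """Planted position-specific dipeptide enrichments for the positive class.

    ``plants`` is a list of (subsite j in 1..2l, dipeptide index in 1..441,
    probability); ``background`` an optional length-20 probability vector over
    the native amino acids (uniform when omitted).
    """

    plants: list[tuple[int, int, float]] = field(default_factory=list)
    background: Sequence[float] | None = None

    def validate(self, half_width: int) -> None:
        l = half_width
        for j, d, p in self.plants:
            if not 1 <= j <= 2 * l:
                raise ContractError(f"plant subsite {j} out of 1..{2 * l}")
            if not 0.0 <= p <= 1.0:
                raise ContractError(f"plant probability {p} out of [0, 1]")
            a, b = dipeptide_symbols(d)
            # subsite j covers 0-based window offsets (j-1, j); offset l is the center
            if j - 1 == l and a != "Y":
                raise DataError(
                    f"plant at subsite {j} writes {a!r} over the central Y"
                )
            if j == l and b != "Y":
                raise DataError(
                    f"plant at subsite {j} writes {b!r} over the central Y"
                )
        if self.background is not None:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (20,) or (bg < 0).any() or abs(bg.sum() - 1.0) > 1e-9:
                raise ContractError(
                    "background must be a length-20 probability vector"
                )


def generate_dataset(
    n_pos: int,
    n_neg: int,
    half_width: int,
    motif: MotifSpec | None = None,
    seed: int = 0,
) -> BenchmarkDataset:
    """Generate a labelled benchmark; deterministic for a given seed.

    Negatives are pure background with a central Y; positives are the same,
    then every plant of the motif overwrites its subsite with its
    probability, in list order.
    """
    if n_pos < 1 or n_neg < 1:
        raise ContractError("n_pos and n_neg must be >= 1")
    motif = motif or MotifSpec()
    motif.validate(half_width)
    rng = np.random.default_rng(seed)
    l = half_width
    width = 2 * l + 1
    bg = (
        np.full(20, 0.05)
        if motif.background is None
        else np.asarray(motif.background, dtype=float)
    )
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

    def make(n: int, plant: bool, label: str, id_offset: int) -> list[PeptideWindow]:
        chars = aa[rng.choice(20, size=(n, width), p=bg)]
        chars[:, l] = ord("Y")
        if plant:
            for j, d, p in motif.plants:
                a, b = dipeptide_symbols(d)
                hit = rng.random(n) < p
                chars[hit, j - 1] = ord(a)
                chars[hit, j] = ord(b)
        return [
            PeptideWindow(
                residues=row.tobytes().decode(),
                half_width=l,
                protein_id=f"SYN{id_offset + i:06d}",
                site_position=l + 1,
                label=label,
            )
            for i, row in enumerate(chars)
        ]

    positives = make(n_pos, True, POSITIVE, 0)
    negatives = make(n_neg, False, NEGATIVE, n_pos)
    return BenchmarkDataset(positives, negatives, half_width)


def default_benchmark_motif(half_width: int = 9) -> MotifSpec:
    """A moderate, fixed enrichment profile for benchmark-shaped fixtures.

    Nitration-prone tyrosines tend to sit in acidic, charged neighbourhoods,
    so the profile plants a handful of acidic/basic dipeptides at scattered
    subsites with probabilities between 0.15 and 0.35 — a visible but far
    from deterministic class contrast.  The two center-touching subsites keep
    Y in the center slot.  Defined once as the package's standard simulated
    condition; not a tuning knob.
    """
    from nitropred.propensity import dipeptide_index as dix

    l = half_width
    if l < 2:
        raise ContractError("default motif requires half_width >= 2")
    # (subsite offset from the window start, dipeptide, probability)
    profile = [
        (1, ("D", "E"), 0.25),
        (max(1, l - 3), ("E", "K"), 0.20),
        (l - 1, ("R", "E"), 0.30),
        (l, ("E", "Y"), 0.35),       # second slot is the central Y
        (l + 1, ("Y", "D"), 0.35),   # first slot is the central Y
        (l + 2, ("K", "D"), 0.20),
        (min(2 * l, l + 4), ("G", "E"), 0.15),
        (2 * l, ("R", "R"), 0.15),
    ]
    seen = set()
    plants = []
    for j, (a, b), p in profile:
        if j in seen:
            continue
        seen.add(j)
        plants.append((j, dix(a, b), p))
    return MotifSpec(plants=plants)


def write_fasta_with_sites(
    dataset: BenchmarkDataset, fasta: IO[str], sites: IO[str]
) -> None:
    """Emit each window as a standalone FASTA record plus an annotation table
    (protein_id <tab> 1-based Y position) for the positive windows, exercising
    the windowing path end to end.

    X padding cannot appear in a protein sequence, so windows are written
    verbatim only when X-free; windows containing X are skipped.
    """
    sites.write("protein_id\tposition\n")
    for windows in (dataset.positives, dataset.negatives):
        for w in windows:
            if "X" in w.residues:
                continue
            fasta.write(f">{w.protein_id}\n{w.residues}\n")
            if w.label == POSITIVE:
                sites.write(f"{w.protein_id}\t{w.half_width + 1}\n")
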