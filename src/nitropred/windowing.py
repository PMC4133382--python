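"""Tyrosine-centered window extraction and benchmark construction.

A candidate nitration site is represented by a (2*l + 1)-mer peptide window
with the tyrosine at its center.  Windows that run past either terminus of
the source protein are padded with the dummy residue ``X``, which is a
first-class symbol of the 21-letter alphabet used throughout the package.
A benchmark dataset is the union of a positive subset (windows whose central
Y is an experimentally confirmed nitrotyrosine) and a negative subset (all
other tyrosine-centered windows of the same proteins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

from nitropred.errors import ContractError, DataError, FormatError

logger = logging.getLogger(__name__)

#: the 20 one-letter amino-acid codes, alphabetical
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: the dummy/padding residue
DUMMY = "X"
#: full residue alphabet of a peptide window
ALPHABET_SYMBOLS = AMINO_ACIDS + DUMMY

#: residue letters that occur in real-world FASTA but are not part of the
#: 20-letter code (ambiguity codes, rare residues, gap/stop marks); they are
#: sanitized to the dummy residue rather than rejected
NONSTANDARD = set("BJOUZ*-")

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an accession-like identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET_SYMBOLS)
        if bad:
            raise DataError(
                f"protein {self.id!r}: unsanitized residue symbols {sorted(bad)}"
            )


@dataclass(frozen=True)
class PeptideWindow:
    """A (2*l + 1)-mer over the 21-symbol alphabet with Y at the center.

    ``site_position`` is the 1-based position of the central tyrosine in the
    source protein, when known.
    """

    residues: str
    half_width: int
    protein_id: str | None = None
    site_position: int | None = None
    label: str = UNLABELED

    def __post_init__(self) -> None:
        l = self.half_width
        if l < 1:
            raise ContractError(f"half_width must be >= 1, got {l}")
        if len(self.residues) != 2 * l + 1:
            raise ContractError(
                f"window {self.residues!r} has length {len(self.residues)}, "
                f"expected {2 * l + 1} for half_width {l}"
            )
        if self.residues[l] != "Y":
            raise ContractError(
                f"window {self.residues!r} center is {self.residues[l]!r}, not 'Y'"
            )
        bad = set(self.residues) - set(ALPHABET_SYMBOLS)
        if bad:
            raise ContractError(
                f"window {self.residues!r} contains invalid symbols {sorted(bad)}"
            )
        if self.label not in (POSITIVE, NEGATIVE, UNLABELED):
            raise ContractError(f"unknown label {self.label!r}")


@dataclass
class BenchmarkDataset:
    """Positive (nitrated) and negative (non-nitrated) windows of one half-width."""

    positives: list[PeptideWindow]
    negatives: list[PeptideWindow]
    half_width: int

    def __post_init__(self) -> None:
        for w in self.positives:
            if w.half_width != self.half_width:
                raise ContractError("positive window half_width mismatch")
            if w.label != POSITIVE:
                raise ContractError("positive subset contains a non-positive label")
        for w in self.negatives:
            if w.half_width != self.half_width:
                raise ContractError("negative window half_width mismatch")
            if w.label != NEGATIVE:
                raise ContractError("negative subset contains a non-negative label")

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def _sanitize(seq: str, record_id: str) -> tuple[str, int]:
    """Uppercase, map non-standard letters to X; returns (clean, n_substituted)."""
    seq = seq.upper()
    n_sub = 0
    out = []
    for ch in seq:
        if ch in NONSTANDARD:
            out.append(DUMMY)
            n_sub += 1
        elif ch in ALPHABET_SYMBOLS:
            out.append(ch)
        else:
            raise FormatError(
                f"protein {record_id!r}: unrecognized residue character {ch!r}"
            )
    return "".join(out), n_sub


def read_fasta(stream: IO[str] | Iterable[str]) -> list[ProteinRecord]:
    """Parse FASTA text into sanitized :class:`ProteinRecord` objects.

    Sequence lines are concatenated, whitespace-stripped and uppercased.
    Non-standard residue letters (B, J, O, U, Z, ``*``, ``-``) are replaced
    by the dummy residue X; the number of substitutions is logged as a
    warning.  Raises :class:`FormatError` on empty input or on sequence data
    appearing before any header, naming the offending line number.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    chunks: list[str] = []
    total_sub = 0
    saw_any = False

    def flush() -> None:
        nonlocal total_sub
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"record {header!r}: no sequence data")
        clean, n_sub = _sanitize(seq, header)
        total_sub += n_sub
        records.append(ProteinRecord(id=header, sequence=clean))

    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        saw_any = True
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if line[1:].split() else line[1:]
            chunks = []
        else:
            if header is None:
                raise FormatError(
                    f"line {lineno}: sequence data before any FASTA header"
                )
            chunks.append("".join(line.split()))
    if not saw_any:
        raise FormatError("empty FASTA input")
    flush()
    if total_sub:
        logger.warning(
            "read_fasta: replaced %d non-standard residue letters with X", total_sub
        )
    return records


def extract_windows(protein: ProteinRecord, half_width: int) -> list[PeptideWindow]:
    """Slide a (2*half_width + 1)-residue window along the protein and emit
    one tyrosine-centered window per Y, in ascending position order.

    For a central position p (1-based) the window spans protein positions
    p - l ... p + l; positions outside the sequence are filled with X.
    """
    if half_width < 1:
        raise ContractError(f"half_width must be >= 1, got {half_width}")
    l = half_width
    seq = protein.sequence
    padded = DUMMY * l + seq + DUMMY * l
    windows = []
    for i, ch in enumerate(seq):
        if ch != "Y":
            continue
        # in `padded`, protein position p (1-based) sits at index p - 1 + l
        start = i  # == (p - 1 + l) - l
        windows.append(
            PeptideWindow(
                residues=padded[start : start + 2 * l + 1],
                half_width=l,
                protein_id=protein.id,
                site_position=i + 1,
                label=UNLABELED,
            )
        )
    return windows


def build_benchmark(
    proteins: Iterable[ProteinRecord],
    annotated_sites: Mapping[str, set[int]],
    half_width: int,
) -> BenchmarkDataset:
    """Partition every tyrosine-centered window into the positive subset
    (central Y annotated as nitrated) or the negative subset (all others).

    Duplicate peptide strings are retained; propensities are occurrence
    frequencies, so each window counts once.  Raises :class:`DataError` if
    an annotated position does not carry a Y or names an absent protein.
    """
    proteins = list(proteins)
    by_id = {p.id: p for p in proteins}
    for pid, sites in annotated_sites.items():
        if pid not in by_id:
            raise DataError(f"annotated protein {pid!r} not among input proteins")
        seq = by_id[pid].sequence
        for pos in sites:
            if pos < 1 or pos > len(seq):
                raise DataError(
                    f"protein {pid!r}: annotated position {pos} out of range"
                )
            if seq[pos - 1] != "Y":
                raise DataError(
                    f"protein {pid!r}: annotated position {pos} is "
                    f"{seq[pos - 1]!r}, not 'Y'"
                )
    positives: list[PeptideWindow] = []
    negatives: list[PeptideWindow] = []
    for prot in proteins:
        sites = annotated_sites.get(prot.id, set())
        for w in extract_windows(prot, half_width):
            if w.site_position in sites:
                positives.append(
                    PeptideWindow(w.residues, w.half_width, w.protein_id,
                                  w.site_position, POSITIVE)
                )
            else:
                negatives.append(
                    PeptideWindow(w.residues, w.half_width, w.protein_id,
                                  w.site_position, NEGATIVE)
                )
    return BenchmarkDataset(positives, negatives, half_width)


def parse_benchmark_table(stream: IO[str] | Iterable[str]) -> BenchmarkDataset:
    """Read the 4-column benchmark TSV dialect into a :class:`BenchmarkDataset`.

    Columns: protein_id, site_position (1-based), peptide, label (1 positive,
    0 negative).  A header line is optional (detected by a non-integer second
    column on the first row); ``#`` comment lines are ignored.  The window
    half-width is inferred from the (odd, uniform) peptide length.
    """
    positives: list[PeptideWindow] = []
    negatives: list[PeptideWindow] = []
    half_width: int | None = None
    first_data_row = True
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(
                f"row {lineno}: expected 4 tab-separated columns, got {len(fields)}"
            )
        pid, pos_s, pep, label_s = (f.strip() for f in fields)
        if first_data_row and not pos_s.lstrip("-").isdigit():
            first_data_row = False
            continue  # header line
        first_data_row = False
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise FormatError(f"row {lineno}: bad site position {pos_s!r}") from exc
        pep = pep.upper()
        if len(pep) % 2 == 0:
            raise FormatError(
                f"row {lineno}: peptide length {len(pep)} is even; windows "
                "must have odd length"
            )
        l = len(pep) // 2
        if half_width is None:
            half_width = l
        elif l != half_width:
            raise FormatError(
                f"row {lineno}: peptide length {len(pep)} inconsistent with "
                f"earlier rows (half_width {half_width})"
            )
        if pep[l] != "Y":
            raise FormatError(
                f"row {lineno}: center residue {pep[l]!r} is not 'Y'"
            )
        if label_s == "1":
            label = POSITIVE
        elif label_s == "0":
            label = NEGATIVE
        else:
            raise FormatError(f"row {lineno}: unknown label token {label_s!r}")
        try:
            w = PeptideWindow(pep, l, pid, pos, label)
        except ContractError as exc:
            raise FormatError(f"row {lineno}: {exc}") from exc
        (positives if label == POSITIVE else negatives).append(w)
    if half_width is None:
        raise FormatError("benchmark table contains no data rows")
    return BenchmarkDataset(positives, negatives, half_width)


def write_benchmark_table(dataset: BenchmarkDataset, stream: IO[str]) -> None:
    """Write a dataset in the 4-column benchmark TSV dialect (with header)."""
    stream.write("protein_id\tsite_position\tpeptide\tlabel\n")
    for windows, tok in ((dataset.positives, "1"), (dataset.negatives, "0")):
        for w in windows:
            stream.write(
                f"{w.protein_id or '.'}\t{w.site_position or 0}\t{w.residues}\t{tok}\n"
            )
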