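"""The discriminant-function classifier over paired propensity matrices.

A window is scored by its similarity to the *ideal* peptide of each class —
the hypothetical window whose every feature component sits at its upper
limit 1.  Since feature components are frequencies in [0, 1], that
similarity is the plain component sum of the feature vector, so

    phi_plus  = sum of the window's positive-matrix lookups   (in [0, 2l])
    phi_minus = sum of the window's negative-matrix lookups   (in [0, 2l])
    delta     = phi_plus - phi_minus + xi

and the window is called a nitration site iff delta >= 0 (the boundary
counts positive).  xi is an additive adjustment chosen to maximize overall
accuracy on heavily imbalanced benchmarks; it is equivalent to moving the
decision threshold on the raw score phi_plus - phi_minus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

import numpy as np

from nitropred.errors import ContractError, EstimationError, FormatError
from nitropred.propensity import (
    DIPEPTIDE,
    N_DIPEPTIDES,
    N_SYMBOLS,
    PropensityMatrix,
    SINGLE_RESIDUE,
    encode_window,
    encode_windows,
)
from nitropred.windowing import BenchmarkDataset, NEGATIVE, POSITIVE, PeptideWindow

MODEL_FORMAT_VERSION = 1


@dataclass
class DiscriminantModel:
    """Trained predictor: paired class propensity matrices plus xi."""

    z_plus: PropensityMatrix
    z_minus: PropensityMatrix
    xi: float
    half_width: int
    encoder_mode: str = DIPEPTIDE

    def __post_init__(self) -> None:
        if self.z_plus.half_width != self.half_width or (
            self.z_minus.half_width != self.half_width
        ):
            raise ContractError("matrix half_width does not match model half_width")
        if self.z_plus.mode != self.encoder_mode or self.z_minus.mode != self.encoder_mode:
            raise ContractError("matrix encoder mode does not match model")


@dataclass(frozen=True)
class SiteScore:
    """Scored candidate site: similarity scores, discriminant and call."""

    protein_id: str | None
    site_position: int | None
    window: str
    phi_plus: float
    phi_minus: float
    delta: float
    call: str


def _phi(codes: np.ndarray, matrix: PropensityMatrix) -> np.ndarray:
    """Component sums of feature vectors for pre-encoded windows (n, 2l).

    Computed as (sum of integer counts) / sample_count so that scores agree
    bit-for-bit however the counts were assembled (full training or
    leave-one-out decrements).
    """
    cols = np.arange(codes.shape[-1])
    return matrix.counts[codes, cols].sum(axis=-1) / matrix.sample_count


def similarity_scores(
    window: PeptideWindow, model: DiscriminantModel
) -> tuple[float, float]:
    """(phi_plus, phi_minus): the window's similarity to each class ideal."""
    if window.half_width != model.half_width:
        raise ContractError(
            f"window half_width {window.half_width} != model {model.half_width}"
        )
    codes = encode_window(window, model.encoder_mode)
    return float(_phi(codes, model.z_plus)), float(_phi(codes, model.z_minus))


def delta(window: PeptideWindow, model: DiscriminantModel) -> float:
    """Discriminant phi_plus - phi_minus + xi."""
    phi_p, phi_m = similarity_scores(window, model)
    return phi_p - phi_m + model.xi


def classify(window: PeptideWindow, model: DiscriminantModel) -> str:
    """'positive' iff delta >= 0, else 'negative'."""
    return POSITIVE if delta(window, model) >= 0.0 else NEGATIVE


def score_site(window: PeptideWindow, model: DiscriminantModel) -> SiteScore:
    phi_p, phi_m = similarity_scores(window, model)
    d = phi_p - phi_m + model.xi
    return SiteScore(
        window.protein_id,
        window.site_position,
        window.residues,
        phi_p,
        phi_m,
        d,
        POSITIVE if d >= 0.0 else NEGATIVE,
    )


def raw_deltas(
    windows: Sequence[PeptideWindow], model: DiscriminantModel
) -> np.ndarray:
    """phi_plus - phi_minus for many windows, without the xi shift."""
    if not windows:
        return np.zeros(0)
    codes = encode_windows(list(windows), model.encoder_mode)
    return _phi(codes, model.z_plus) - _phi(codes, model.z_minus)


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if lab in (POSITIVE, 1, True, "+", "1"):
            out[i] = True
        elif lab in (NEGATIVE, 0, False, "-", "0"):
            out[i] = False
        else:
            raise ContractError(f"unrecognized label {lab!r}")
    return out


def _acc_mcc(tp: np.ndarray, fp: np.ndarray, tn: np.ndarray, fn: np.ndarray):
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    den = np.sqrt(
        (tp + fp).astype(float) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mcc = np.where(den > 0, (tp * tn - fp * fn) / np.where(den > 0, den, 1.0), 0.0)
    return acc, mcc


def tune_xi(raw: Sequence[float], labels: Sequence) -> float:
    """Choose xi maximizing overall accuracy of the rule raw + xi >= 0.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted raw scores plus guards beyond both extremes; xi = -t* for the
    accuracy-maximizing threshold t*, with ties broken by higher MCC and
    then by smaller absolute xi.  Requires scores from both classes.
    """
    raw = np.asarray(raw, dtype=float)
    y = _as_bool_labels(labels)
    if raw.size != y.size:
        raise ContractError("raw scores and labels differ in length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EstimationError("xi tuning requires scores from both classes")
    distinct = np.unique(raw)
    candidates = np.concatenate(
        [[distinct[0] - 1.0], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1] + 1.0]]
    )
    pos_sorted = np.sort(raw[y])
    neg_sorted = np.sort(raw[~y])
    # predict positive iff raw >= t
    tp = n_pos - np.searchsorted(pos_sorted, candidates, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, candidates, side="left")
    fn = n_pos - tp
    tn = n_neg - fp
    acc, mcc = _acc_mcc(tp, fp, tn, fn)
    xi_cand = -candidates
    # lexicographic: max Acc, then max MCC, then min |xi|
    order = np.lexsort((np.abs(xi_cand), -mcc, -acc))
    return float(xi_cand[order[0]])


def train(
    dataset: BenchmarkDataset,
    encoder_mode: str = DIPEPTIDE,
    xi_policy: str | tuple[str, float] = "tuned",
) -> DiscriminantModel:
    """Estimate both class matrices and set xi.

    xi_policy is ``("fixed", value)`` or ``"tuned"`` (threshold search on the
    training set's raw discriminant scores).
    """
    from nitropred.propensity import compute_psap, compute_psdp

    if not dataset.positives or not dataset.negatives:
        raise EstimationError("training requires non-empty positive and negative sets")
    estimator = compute_psdp if encoder_mode == DIPEPTIDE else compute_psap
    if encoder_mode not in (DIPEPTIDE, SINGLE_RESIDUE):
        raise ContractError(f"unknown encoder mode {encoder_mode!r}")
    z_plus = estimator(dataset.positives, dataset.half_width, POSITIVE)
    z_minus = estimator(dataset.negatives, dataset.half_width, NEGATIVE)
    model = DiscriminantModel(z_plus, z_minus, 0.0, dataset.half_width, encoder_mode)
    if xi_policy == "tuned":
        windows = list(dataset.positives) + list(dataset.negatives)
        labels = [POSITIVE] * len(dataset.positives) + [NEGATIVE] * len(dataset.negatives)
        model.xi = tune_xi(raw_deltas(windows, model), labels)
    elif isinstance(xi_policy, tuple) and len(xi_policy) == 2 and xi_policy[0] == "fixed":
        model.xi = float(xi_policy[1])
    else:
        raise ContractError(f"unknown xi policy {xi_policy!r}")
    return model


# ---------------------------------------------------------------------------
# model file: self-describing text, sparse triplets, bit-exact round trip
# ---------------------------------------------------------------------------

def save_model(model: DiscriminantModel, stream: IO[str]) -> None:
    stream.write("# nitropred discriminant model\n")
    stream.write(f"version: {MODEL_FORMAT_VERSION}\n")
    stream.write(f"half_width: {model.half_width}\n")
    stream.write(f"encoder_mode: {model.encoder_mode}\n")
    stream.write(f"xi: {model.xi!r}\n")
    stream.write(f"n_positive: {model.z_plus.sample_count}\n")
    stream.write(f"n_negative: {model.z_minus.sample_count}\n")
    for tag, m in (("positive", model.z_plus), ("negative", model.z_minus)):
        stream.write(f"matrix: {tag}\n")
        rows, cols = np.nonzero(m.counts)
        for r, c in zip(rows, cols):
            freq = m.counts[r, c].item() / m.sample_count
            stream.write(f"{r + 1}\t{c + 1}\t{freq!r}\n")
    stream.write("end\n")


def load_model(stream: IO[str] | Iterable[str]) -> DiscriminantModel:
    header: dict[str, str] = {}
    matrices: dict[str, np.ndarray] = {}
    current: np.ndarray | None = None
    n_by_tag: dict[str, int] = {}
    width = None
    n_rows = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "end":
            break
        if line.startswith("matrix:"):
            for key in ("version", "half_width", "encoder_mode", "xi",
                        "n_positive", "n_negative"):
                if key not in header:
                    raise FormatError(f"model header missing {key!r}")
            l = int(header["half_width"])
            width = 2 * l
            mode = header["encoder_mode"]
            n_rows = N_DIPEPTIDES if mode == DIPEPTIDE else N_SYMBOLS
            tag = line.split(":", 1)[1].strip()
            if tag not in ("positive", "negative"):
                raise FormatError(f"line {lineno}: unknown matrix tag {tag!r}")
            current = np.zeros((n_rows, width), dtype=np.int64)
            matrices[tag] = current
            n_by_tag[tag] = int(header["n_positive" if tag == "positive" else "n_negative"])
            continue
        if ":" in line and current is None:
            key, _, val = line.partition(":")
            header[key.strip()] = val.strip()
            continue
        if current is None:
            raise FormatError(f"line {lineno}: triplet outside any matrix section")
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"line {lineno}: expected 3 triplet fields")
        r, c, freq = int(parts[0]) - 1, int(parts[1]) - 1, float(parts[2])
        if not (0 <= r < n_rows and 0 <= c < width):
            raise FormatError(f"line {lineno}: triplet indices out of range")
        tag = "positive" if current is matrices.get("positive") else "negative"
        count = freq * n_by_tag[tag]
        current[r, c] = int(round(count))
    if set(matrices) != {"positive", "negative"}:
        raise FormatError("model file must contain both class matrices")
    if int(header["version"]) != MODEL_FORMAT_VERSION:
        raise FormatError(f"unsupported model format version {header['version']}")
    l = int(header["half_width"])
    mode = header["encoder_mode"]
    z_plus = PropensityMatrix(
        matrices["positive"], n_by_tag["positive"], l, POSITIVE, mode
    )
    z_minus = PropensityMatrix(
        matrices["negative"], n_by_tag["negative"], l, NEGATIVE, mode
    )
    return DiscriminantModel(z_plus, z_minus, float(header["xi"]), l, mode)
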