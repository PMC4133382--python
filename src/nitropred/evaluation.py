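"""Predictor quality assessment: metrics, jackknife, k-fold and ROC.

The four quality metrics (sensitivity, specificity, overall accuracy and
Matthews correlation coefficient) are computed in two algebraically
equivalent formulations and cross-checked on every call: the familiar
TP/TN/FP/FN form, and the intuitive form over the class sizes N+ and N- and
the misclassification counts N+- (positives called negative) and N-+
(negatives called positive):

    Sn  = 1 - N+-/N+
    Sp  = 1 - N-+/N-
    Acc = 1 - (N+- + N-+)/(N+ + N-)
    MCC = (1 - (N+-/N+ + N-+/N-))
          / sqrt((1 + (N-+ - N+-)/N+) * (1 + (N+- - N-+)/N-))

The leave-one-out jackknife is the evaluation of record: each peptide is
scored by a model trained on the remaining peptides.  Because propensity
matrices are occurrence counts, leaving a peptide out is a decrement of its
own dipeptide counts and a renormalization by n - 1 — no retraining loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from nitropred.discriminant import (
    DiscriminantModel,
    SiteScore,
    _as_bool_labels,
    train,
    tune_xi,
)
from nitropred.errors import ContractError, EvaluationError
from nitropred.propensity import (
    DIPEPTIDE,
    N_DIPEPTIDES,
    N_SYMBOLS,
    counts_from_codes,
    encode_windows,
)
from nitropred.windowing import BenchmarkDataset, NEGATIVE, POSITIVE, PeptideWindow


@dataclass(frozen=True)
class ConfusionCounts:
    """Class sizes and misclassification counts.

    n_plus_to_minus is the number of true positives called negative (= FN);
    n_minus_to_plus the number of true negatives called positive (= FP).
    """

    n_plus: int
    n_minus: int
    n_plus_to_minus: int
    n_minus_to_plus: int

    def __post_init__(self) -> None:
        if min(self.n_plus, self.n_minus, self.n_plus_to_minus, self.n_minus_to_plus) < 0:
            raise ContractError("confusion counts must be non-negative")
        if self.n_plus_to_minus > self.n_plus:
            raise ContractError("N+- cannot exceed N+")
        if self.n_minus_to_plus > self.n_minus:
            raise ContractError("N-+ cannot exceed N-")

    @property
    def tp(self) -> int:
        return self.n_plus - self.n_plus_to_minus

    @property
    def fn(self) -> int:
        return self.n_plus_to_minus

    @property
    def tn(self) -> int:
        return self.n_minus - self.n_minus_to_plus

    @property
    def fp(self) -> int:
        return self.n_minus_to_plus


@dataclass
class MetricsReport:
    """The four metrics plus optional ROC/AUC and protocol annotations."""

    counts: ConfusionCounts
    sn: float
    sp: float
    acc: float
    mcc: float
    mcc_defined: bool = True
    roc: list[tuple[float, float]] | None = None
    auc: float | None = None
    annotations: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [
            f"n_positive\t{self.counts.n_plus}",
            f"n_negative\t{self.counts.n_minus}",
            f"pos_called_neg\t{self.counts.n_plus_to_minus}",
            f"neg_called_pos\t{self.counts.n_minus_to_plus}",
            f"sensitivity\t{self.sn:.6f}",
            f"specificity\t{self.sp:.6f}",
            f"accuracy\t{self.acc:.6f}",
            f"mcc\t{self.mcc:.6f}",
            f"mcc_defined\t{self.mcc_defined}",
        ]
        if self.auc is not None:
            lines.append(f"auc\t{self.auc:.6f}")
        for key in sorted(self.annotations):
            lines.append(f"{key}\t{self.annotations[key]}")
        return "\n".join(lines) + "\n"

    def to_frame(self) -> pd.DataFrame:
        row = {
            "n_positive": self.counts.n_plus,
            "n_negative": self.counts.n_minus,
            "pos_called_neg": self.counts.n_plus_to_minus,
            "neg_called_pos": self.counts.n_minus_to_plus,
            "sensitivity": self.sn,
            "specificity": self.sp,
            "accuracy": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
        }
        row.update(self.annotations)
        return pd.DataFrame([row])


_XCHECK_TOL = 1e-12


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Compute Sn/Sp/Acc/MCC in both formulations and cross-check them.

    MCC with a zero denominator (a degenerate predicted or true margin) is
    reported as 0 with ``mcc_defined=False``.
    """
    np_, nm = counts.n_plus, counts.n_minus
    npm, nmp = counts.n_plus_to_minus, counts.n_minus_to_plus
    if np_ == 0 or nm == 0:
        raise EvaluationError("Sn/Sp require at least one sample per class")

    # intuitive class-size formulation
    sn = 1.0 - npm / np_
    sp = 1.0 - nmp / nm
    acc = 1.0 - (npm + nmp) / (np_ + nm)
    mcc_num = 1.0 - (npm / np_ + nmp / nm)
    mcc_den_sq = (1.0 + (nmp - npm) / np_) * (1.0 + (npm - nmp) / nm)

    # TP/TN/FP/FN formulation
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    sn2 = tp / (tp + fn)
    sp2 = tn / (tn + fp)
    acc2 = (tp + tn) / (tp + tn + fp + fn)
    den = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))

    for a, b, name in ((sn, sn2, "Sn"), (sp, sp2, "Sp"), (acc, acc2, "Acc")):
        if abs(a - b) > _XCHECK_TOL:
            raise AssertionError(f"metric formulations disagree on {name}: {a} vs {b}")

    if den > 0.0:
        mcc2 = (tp * tn - fp * fn) / den
        mcc = mcc_num / math.sqrt(mcc_den_sq)
        if abs(mcc - mcc2) > _XCHECK_TOL:
            raise AssertionError(f"MCC formulations disagree: {mcc} vs {mcc2}")
        return MetricsReport(counts, sn, sp, acc, mcc2)
    return MetricsReport(counts, sn, sp, acc, 0.0, mcc_defined=False)


def _counts_from_calls(
    pos_called_pos: np.ndarray, neg_called_pos: np.ndarray
) -> ConfusionCounts:
    return ConfusionCounts(
        n_plus=pos_called_pos.size,
        n_minus=neg_called_pos.size,
        n_plus_to_minus=int((~pos_called_pos).sum()),
        n_minus_to_plus=int(neg_called_pos.sum()),
    )


def _dataset_codes(dataset: BenchmarkDataset, encoder_mode: str):
    dp = encode_windows(list(dataset.positives), encoder_mode)
    dn = encode_windows(list(dataset.negatives), encoder_mode)
    n_rows = N_DIPEPTIDES if encoder_mode == DIPEPTIDE else N_SYMBOLS
    cp = counts_from_codes(dp, n_rows)
    cn = counts_from_codes(dn, n_rows)
    return dp, dn, cp, cn


def _gather(counts: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Per-window sums of count-table lookups, shape (n,)."""
    cols = np.arange(codes.shape[1])
    return counts[codes, cols].sum(axis=1)


def jackknife(
    dataset: BenchmarkDataset,
    encoder_mode: str = DIPEPTIDE,
    xi_policy: str | tuple[str, float] = "shared",
) -> tuple[MetricsReport, list[SiteScore]]:
    """Leave-one-out evaluation with decremental count updates.

    Each sample is scored by matrices in which its own class's counts are
    decremented by the sample's contribution and renormalized by n - 1; the
    opposite-class matrix is untouched.  xi policies:

    - ``("fixed", v)``: use v throughout;
    - ``"shared"`` (default): xi tuned once on the full dataset's raw
      discriminant scores, then held fixed across the leave-one-out scoring;
    - ``"tuned"``: re-tuned for every held-out sample on the remaining
      samples' leave-one-out raw scores (leakage-free but O(n^2); intended
      for small datasets).

    Returns the pooled metrics report (with ROC/AUC over the raw scores) and
    the per-sample site scores.  Deterministic.
    """
    if len(dataset.positives) < 2 or len(dataset.negatives) < 2:
        raise EvaluationError("jackknife requires at least 2 samples per class")
    dp, dn, cp, cn = _dataset_codes(dataset, encoder_mode)
    n_pos, n_neg = dp.shape[0], dn.shape[0]

    # leave-one-out raw scores: own-class lookups lose the sample's own
    # contribution (exactly 1 per subsite) and renormalize by n - 1
    raw_pos = (_gather(cp, dp) - dp.shape[1]) / (n_pos - 1) - _gather(cn, dp) / n_neg
    raw_neg = _gather(cp, dn) / n_pos - (_gather(cn, dn) - dn.shape[1]) / (n_neg - 1)
    raw = np.concatenate([raw_pos, raw_neg])
    labels = [POSITIVE] * n_pos + [NEGATIVE] * n_neg

    if isinstance(xi_policy, tuple) and xi_policy and xi_policy[0] == "fixed":
        xi = np.full(raw.size, float(xi_policy[1]))
        xi_note = f"fixed({xi_policy[1]})"
    elif xi_policy == "shared":
        full_raw = np.concatenate(
            [_gather(cp, dp) / n_pos - _gather(cn, dp) / n_neg,
             _gather(cp, dn) / n_pos - _gather(cn, dn) / n_neg]
        )
        shared = tune_xi(full_raw, labels)
        xi = np.full(raw.size, shared)
        xi_note = f"shared({shared!r})"
    elif xi_policy == "tuned":
        xi = _nested_jackknife_xi(dp, dn, cp, cn)
        xi_note = "nested"
    else:
        raise ContractError(f"unknown xi policy {xi_policy!r}")

    deltas = raw + xi
    called_pos = deltas >= 0.0
    counts = _counts_from_calls(called_pos[:n_pos], called_pos[n_pos:])
    report = metrics(counts)
    points, auc = roc_curve(raw, labels)
    report.roc, report.auc = points, auc
    report.annotations.update(
        {"protocol": "jackknife", "encoder": encoder_mode, "xi_policy": xi_note}
    )

    windows = list(dataset.positives) + list(dataset.negatives)
    phis_plus = np.concatenate([
        (_gather(cp, dp) - dp.shape[1]) / (n_pos - 1), _gather(cp, dn) / n_pos
    ])
    phis_minus = np.concatenate([
        _gather(cn, dp) / n_neg, (_gather(cn, dn) - dn.shape[1]) / (n_neg - 1)
    ])
    scores = [
        SiteScore(
            w.protein_id, w.site_position, w.residues,
            float(pp), float(pm), float(d),
            POSITIVE if c else NEGATIVE,
        )
        for w, pp, pm, d, c in zip(windows, phis_plus, phis_minus, deltas, called_pos)
    ]
    return report, scores


def _nested_jackknife_xi(
    dp: np.ndarray, dn: np.ndarray, cp: np.ndarray, cn: np.ndarray
) -> np.ndarray:
    """Per-held-out-sample xi, tuned on the remaining samples' scores under
    the leave-one-out matrices.  Quadratic in the dataset size."""
    n_pos, n_neg = dp.shape[0], dn.shape[0]
    width = dp.shape[1]
    labels_wo_pos = [POSITIVE] * (n_pos - 1) + [NEGATIVE] * n_neg
    labels_wo_neg = [POSITIVE] * n_pos + [NEGATIVE] * (n_neg - 1)
    xis = np.empty(n_pos + n_neg)
    cols = np.arange(width)
    for i in range(n_pos):
        cp_i = cp.copy()
        np.subtract.at(cp_i, (dp[i], cols), 1)
        others_p = np.delete(dp, i, axis=0)
        raw_others = np.concatenate([
            _gather(cp_i, others_p) / (n_pos - 1) - _gather(cn, others_p) / n_neg,
            _gather(cp_i, dn) / (n_pos - 1) - _gather(cn, dn) / n_neg,
        ])
        xis[i] = tune_xi(raw_others, labels_wo_pos)
    for i in range(n_neg):
        cn_i = cn.copy()
        np.subtract.at(cn_i, (dn[i], cols), 1)
        others_n = np.delete(dn, i, axis=0)
        raw_others = np.concatenate([
            _gather(cp, dp) / n_pos - _gather(cn_i, dp) / (n_neg - 1),
            _gather(cp, others_n) / n_pos - _gather(cn_i, others_n) / (n_neg - 1),
        ])
        xis[n_pos + i] = tune_xi(raw_others, labels_wo_neg)
    return xis


def kfold(
    dataset: BenchmarkDataset,
    k: int,
    seed: int,
    encoder_mode: str = DIPEPTIDE,
    xi_policy: str | tuple[str, float] = "shared",
) -> MetricsReport:
    """Stratified k-fold cross-validation with pooled (micro-averaged) counts.

    Folds: each class is shuffled with a seeded generator, the shuffled
    positives followed by the shuffled negatives are dealt round-robin into
    the k folds (continuing the cycle across the class boundary), so class
    proportions per fold are balanced to within one sample and k equal to the
    dataset size degenerates to leave-one-out.  xi policies as in
    :func:`jackknife`, with ``"tuned"`` re-tuning on each fold's training
    scores.  The fold assignment is recorded in the report annotations.
    """
    n_pos, n_neg = len(dataset.positives), len(dataset.negatives)
    n_tot = n_pos + n_neg
    if k < 2 or k > n_tot:
        raise EvaluationError(f"k must be in [2, {n_tot}], got {k}")
    if min(n_pos, n_neg) < 2:
        raise EvaluationError("k-fold requires at least 2 samples per class")
    rng = np.random.default_rng(seed)
    perm_pos = rng.permutation(n_pos)
    perm_neg = rng.permutation(n_neg)
    # fold ids in dataset order (positives then negatives)
    fold = np.empty(n_tot, dtype=np.int64)
    fold[perm_pos] = np.arange(n_pos) % k
    fold[n_pos + perm_neg] = (n_pos + np.arange(n_neg)) % k

    dp, dn, cp, cn = _dataset_codes(dataset, encoder_mode)
    fold_pos, fold_neg = fold[:n_pos], fold[n_pos:]

    if isinstance(xi_policy, tuple) and xi_policy and xi_policy[0] == "fixed":
        shared_xi: float | None = float(xi_policy[1])
        xi_note = f"fixed({xi_policy[1]})"
    elif xi_policy == "shared":
        full_raw = np.concatenate(
            [_gather(cp, dp) / n_pos - _gather(cn, dp) / n_neg,
             _gather(cp, dn) / n_pos - _gather(cn, dn) / n_neg]
        )
        shared_xi = tune_xi(full_raw, [POSITIVE] * n_pos + [NEGATIVE] * n_neg)
        xi_note = f"shared({shared_xi!r})"
    elif xi_policy == "tuned":
        shared_xi = None
        xi_note = "per-fold"
    else:
        raise ContractError(f"unknown xi policy {xi_policy!r}")

    raw = np.empty(n_tot)
    deltas = np.empty(n_tot)
    n_rows = cp.shape[0]
    for f in range(k):
        test_p = fold_pos == f
        test_n = fold_neg == f
        train_np = int((~test_p).sum())
        train_nn = int((~test_n).sum())
        if train_np == 0 or train_nn == 0:
            raise EvaluationError(
                f"fold {f}: training set lost an entire class; reduce k"
            )
        cp_f = cp - counts_from_codes(dp[test_p], n_rows) if test_p.any() else cp
        cn_f = cn - counts_from_codes(dn[test_n], n_rows) if test_n.any() else cn
        if shared_xi is None:
            train_raw = np.concatenate([
                _gather(cp_f, dp[~test_p]) / train_np - _gather(cn_f, dp[~test_p]) / train_nn,
                _gather(cp_f, dn[~test_n]) / train_np - _gather(cn_f, dn[~test_n]) / train_nn,
            ])
            train_labels = [POSITIVE] * train_np + [NEGATIVE] * train_nn
            xi_f = tune_xi(train_raw, train_labels)
        else:
            xi_f = shared_xi
        if test_p.any():
            rp = _gather(cp_f, dp[test_p]) / train_np - _gather(cn_f, dp[test_p]) / train_nn
            raw[np.flatnonzero(test_p)] = rp
            deltas[np.flatnonzero(test_p)] = rp + xi_f
        if test_n.any():
            rn = _gather(cp_f, dn[test_n]) / train_np - _gather(cn_f, dn[test_n]) / train_nn
            raw[n_pos + np.flatnonzero(test_n)] = rn
            deltas[n_pos + np.flatnonzero(test_n)] = rn + xi_f

    called_pos = deltas >= 0.0
    counts = _counts_from_calls(called_pos[:n_pos], called_pos[n_pos:])
    report = metrics(counts)
    labels = [POSITIVE] * n_pos + [NEGATIVE] * n_neg
    points, auc = roc_curve(raw, labels)
    report.roc, report.auc = points, auc
    report.annotations.update(
        {
            "protocol": f"{k}-fold",
            "encoder": encoder_mode,
            "xi_policy": xi_note,
            "seed": seed,
            "fold_assignment": fold.tolist(),
        }
    )
    return report


def roc_curve(
    raw: Sequence[float], labels: Sequence
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (1 - Sp, Sn) over all distinct score thresholds, plus AUC.

    The threshold sweeps from above the maximum score (no positives called)
    down through every distinct observed score, i.e. over every achievable
    xi; the area under the curve is the trapezoidal integral.
    """
    raw = np.asarray(raw, dtype=float)
    y = _as_bool_labels(labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC requires scores from both classes")
    order = np.argsort(-raw, kind="stable")
    sorted_y = y[order]
    sorted_s = raw[order]
    tps = np.cumsum(sorted_y)
    fps = np.cumsum(~sorted_y)
    # keep the last point of each tied-score block
    distinct = np.r_[sorted_s[1:] != sorted_s[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def window_size_sweep(
    proteins: Iterable,
    annotated_sites: Mapping[str, set[int]],
    half_widths: Sequence[int],
    k: int,
    seed: int,
    encoder_mode: str = DIPEPTIDE,
    xi_policy: str | tuple[str, float] = "shared",
) -> pd.DataFrame:
    """k-fold AUC per candidate window half-width.

    Builds one benchmark per half-width from the same proteins/annotations,
    runs stratified k-fold with the given seed and reports the pooled
    out-of-fold AUC; one row per requested half-width.
    """
    from nitropred.windowing import build_benchmark

    if not half_widths:
        raise EvaluationError("half_widths must be non-empty")
    proteins = list(proteins)
    rows = []
    for l in half_widths:
        ds = build_benchmark(proteins, annotated_sites, l)
        report = kfold(ds, k, seed, encoder_mode, xi_policy)
        rows.append({"half_width": l, "auc": report.auc,
                     "accuracy": report.acc, "mcc": report.mcc})
    return pd.DataFrame(rows)
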