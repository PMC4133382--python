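import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from conftest import random_dataset, win
from nitropred.discriminant import train, raw_deltas
from nitropred.errors import ContractError, EvaluationError
from nitropred.evaluation import (
    ConfusionCounts,
    jackknife,
    kfold,
    metrics,
    roc_curve,
    window_size_sweep,
)
from nitropred.propensity import dipeptide_index
from nitropred.synthetic import MotifSpec, generate_dataset, write_fasta_with_sites
from nitropred.windowing import (
    BenchmarkDataset,
    NEGATIVE,
    POSITIVE,
    build_benchmark,
    read_fasta,
)


def expand_counts(c: ConfusionCounts):
    """Per-sample label/prediction vectors equivalent to the counts."""
    y = [1] * c.n_plus + [0] * c.n_minus
    pred = (
        [1] * c.tp + [0] * c.fn + [0] * c.tn + [1] * c.fp
    )
    return y, pred


class TestMetrics:
    def test_worked_example_against_confusion_oracle(self):
        r = metrics(ConfusionCounts(10, 90, 2, 9))
        assert (r.sn, r.sp, r.acc) == (0.8, 0.9, 0.89)
        y, pred = expand_counts(r.counts)
        assert r.mcc == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)
        assert r.mcc == pytest.approx(0.559, abs=5e-4)

    def test_perfect_and_all_wrong_limits(self):
        perfect = metrics(ConfusionCounts(5, 7, 0, 0))
        assert (perfect.sn, perfect.sp, perfect.acc, perfect.mcc) == (1, 1, 1, 1)
        worst = metrics(ConfusionCounts(5, 7, 5, 7))
        assert (worst.sn, worst.sp, worst.acc, worst.mcc) == (0, 0, 0, -1)

    def test_zero_denominator_mcc_is_flagged_zero(self):
        r = metrics(ConfusionCounts(4, 6, 4, 0))  # everything called negative
        assert r.mcc == 0.0 and not r.mcc_defined

    @pytest.mark.parametrize(
        "args", [(-1, 5, 0, 0), (5, 5, 6, 0), (5, 5, 0, 6)]
    )
    def test_invalid_counts_are_contract_errors(self, args):
        with pytest.raises(ContractError):
            ConfusionCounts(*args)

    def test_both_formulations_agree_on_random_tables(self):
        """Class-size/misclassification form vs TP/TN/FP/FN form, 1000 tables."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n_plus = int(rng.integers(1, 200))
            n_minus = int(rng.integers(1, 200))
            c = ConfusionCounts(
                n_plus, n_minus,
                int(rng.integers(0, n_plus + 1)),
                int(rng.integers(0, n_minus + 1)),
            )
            r = metrics(c)  # raises internally if the formulations disagree
            tp, fn, tn, fp = c.tp, c.fn, c.tn, c.fp
            assert r.sn == pytest.approx(tp / (tp + fn), abs=1e-12)
            assert r.sp == pytest.approx(tn / (tn + fp), abs=1e-12)
            assert r.acc == pytest.approx((tp + tn) / (n_plus + n_minus), abs=1e-12)
            if r.mcc_defined:
                y, pred = expand_counts(c)
                assert r.mcc == pytest.approx(matthews_corrcoef(y, pred), abs=1e-9)


class TestJackknife:
    def test_twin_peptides_are_recovered(self):
        ds = BenchmarkDataset(
            [win("AYC", POSITIVE)] * 2, [win("GYG", NEGATIVE)] * 2, 1
        )
        report, scores = jackknife(ds, xi_policy=("fixed", 0.0))
        assert report.acc == 1.0
        assert [s.call for s in scores] == [POSITIVE] * 2 + [NEGATIVE] * 2

    def test_decremental_update_equals_full_retrain(self):
        """Leave-one-out by count decrement must match training from scratch
        on the n-1 remaining samples, sample by sample, exactly."""
        ds = random_dataset(9, 14, 2, seed=31)
        _, scores = jackknife(ds, xi_policy=("fixed", 0.0))
        windows = list(ds.positives) + list(ds.negatives)
        for i, held_out in enumerate(windows):
            pos = [w for j, w in enumerate(ds.positives) if j != i]
            neg = [
                w for j, w in enumerate(ds.negatives) if j != i - len(ds.positives)
            ]
            model = train(BenchmarkDataset(pos, neg, 2), xi_policy=("fixed", 0.0))
            expected = float(raw_deltas([held_out], model)[0])
            assert scores[i].delta == expected

    def test_symmetric_classes_score_zero(self):
        ds = BenchmarkDataset(
            [win("AYC", POSITIVE)] * 2, [win("AYC", NEGATIVE)] * 2, 1
        )
        _, scores = jackknife(ds, xi_policy=("fixed", 0.0))
        assert all(s.delta == 0.0 and s.call == POSITIVE for s in scores)

    def test_requires_two_samples_per_class(self):
        ds = BenchmarkDataset(
            [win("AYC", POSITIVE)], [win("GYG", NEGATIVE)] * 3, 1
        )
        with pytest.raises(EvaluationError):
            jackknife(ds)

    def test_nested_xi_runs_and_is_deterministic(self):
        ds = generate_dataset(
            12, 18, 2, MotifSpec(plants=[(1, dipeptide_index("A", "A"), 0.9)]), seed=4
        )
        r1, s1 = jackknife(ds, xi_policy="tuned")
        r2, s2 = jackknife(ds, xi_policy="tuned")
        assert [s.delta for s in s1] == [s.delta for s in s2]
        assert r1.acc == r2.acc


class TestKfold:
    def test_same_seed_same_report(self):
        ds = generate_dataset(
            30, 50, 2, MotifSpec(plants=[(1, dipeptide_index("A", "A"), 0.8)]), seed=9
        )
        r1 = kfold(ds, 5, seed=7)
        r2 = kfold(ds, 5, seed=7)
        assert r1.to_text() == r2.to_text()
        assert r1.annotations["fold_assignment"] == r2.annotations["fold_assignment"]

    def test_k_equal_to_dataset_size_degenerates_to_jackknife(self):
        ds = random_dataset(6, 10, 2, seed=17)
        loo = kfold(ds, len(ds), seed=0, xi_policy="shared")
        jk, _ = jackknife(ds, xi_policy="shared")
        assert loo.counts == jk.counts
        assert loo.acc == jk.acc and loo.mcc == jk.mcc

    def test_strong_signal_gives_high_accuracy(self):
        motif = MotifSpec(
            plants=[
                (1, dipeptide_index("A", "A"), 0.95),
                (4, dipeptide_index("W", "W"), 0.95),
            ]
        )
        ds = generate_dataset(120, 120, 2, motif, seed=12)
        report = kfold(ds, 10, seed=1)
        assert report.acc > 0.95

    def test_bad_k_is_an_evaluation_error(self):
        ds = random_dataset(5, 5, 1, seed=2)
        with pytest.raises(EvaluationError):
            kfold(ds, 1, seed=0)
        with pytest.raises(EvaluationError):
            kfold(ds, 11, seed=0)


class TestRoc:
    def test_perfect_separation(self):
        _, auc = roc_curve([3, 2, 1, 0], [POSITIVE, POSITIVE, NEGATIVE, NEGATIVE])
        assert auc == 1.0

    def test_label_free_scores_give_half(self):
        rng = np.random.default_rng(2024)
        scores = rng.normal(size=2000)
        labels = [POSITIVE if b else NEGATIVE for b in rng.random(2000) < 0.5]
        _, auc = roc_curve(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_auc_equals_normalized_mann_whitney_u(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            pos = rng.normal(0.3, 1.0, size=40)
            neg = rng.normal(0.0, 1.0, size=60)
            scores = np.concatenate([pos, neg]).round(1)  # force ties
            labels = [POSITIVE] * 40 + [NEGATIVE] * 60
            _, auc = roc_curve(scores, labels)
            u = mannwhitneyu(scores[:40], scores[40:], alternative="two-sided")
            assert auc == pytest.approx(u.statistic / (40 * 60), abs=1e-12)
            y = [1] * 40 + [0] * 60
            assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_points_are_monotone(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=100)
        labels = [POSITIVE if b else NEGATIVE for b in rng.random(100) < 0.3]
        points, _ = roc_curve(scores, labels)
        xs, ys = zip(*points)
        assert all(a <= b for a, b in zip(xs, xs[1:]))
        assert all(a <= b for a, b in zip(ys, ys[1:]))
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_single_class_is_an_error(self):
        with pytest.raises(EvaluationError):
            roc_curve([1.0, 2.0], [POSITIVE, POSITIVE])


def _windows_as_proteins(half_width, motif, n_pos, n_neg, seed):
    """Turn synthetic windows into standalone proteins + site annotations."""
    import io

    # background with no Y in flanks, so each protein has exactly one Y
    bg = np.full(20, 1 / 19)
    bg[list("ACDEFGHIKLMNPQRSTVWY").index("Y")] = 0.0
    motif.background = bg
    ds = generate_dataset(n_pos, n_neg, half_width, motif, seed)
    fasta, sites = io.StringIO(), io.StringIO()
    write_fasta_with_sites(ds, fasta, sites)
    proteins = read_fasta(io.StringIO(fasta.getvalue()))
    annotated = {}
    for line in sites.getvalue().splitlines()[1:]:
        pid, pos = line.split("\t")
        annotated.setdefault(pid, set()).add(int(pos))
    return proteins, annotated


class TestWindowSizeSweep:
    def test_one_row_per_half_width_and_signal_containment(self):
        """Signal planted only at the outermost subsites of an l=2 window is
        fully visible at l=2 but clipped at l=1."""
        motif = MotifSpec(
            plants=[
                (1, dipeptide_index("A", "A"), 0.9),
                (4, dipeptide_index("W", "W"), 0.9),
            ]
        )
        proteins, annotated = _windows_as_proteins(2, motif, 80, 120, seed=33)
        table = window_size_sweep(proteins, annotated, [1, 2], k=5, seed=3)
        assert list(table["half_width"]) == [1, 2]
        auc = dict(zip(table["half_width"], table["auc"]))
        assert auc[2] >= auc[1]

    def test_sweep_over_single_width_matches_kfold(self):
        motif = MotifSpec(plants=[(1, dipeptide_index("A", "A"), 0.7)])
        proteins, annotated = _windows_as_proteins(2, motif, 40, 60, seed=8)
        table = window_size_sweep(proteins, annotated, [2], k=4, seed=5)
        ds = build_benchmark(proteins, annotated, 2)
        report = kfold(ds, 4, seed=5)
        assert table.loc[0, "auc"] == report.auc
        assert table.loc[0, "accuracy"] == report.acc
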