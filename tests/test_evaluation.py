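"""Metric implementations against independent brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from bpsubtype.evaluation import (
    auroc,
    average_precision,
    best_f1_threshold,
    confusion_at_threshold,
    f1_with_fold_threshold,
    misclassification_feature_summary,
    paired_fold_test,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def auroc_by_pairwise_concordance(scores, labels):
    """O(n^2) probability a random positive outranks a random negative,
    ties counted one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def ap_by_threshold_enumeration(scores, labels):
    """Step-wise AP by walking descending unique thresholds."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(y.sum())
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        called = s >= t
        tp = int((y[called] == 1).sum())
        precision = tp / called.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def f1_by_exhaustive_enumeration(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    best = -1.0
    thresholds = np.concatenate([[-np.inf], np.sort(np.unique(s)), [np.inf]])
    for t in thresholds:
        pred = (s > t).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        f1 = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
        best = max(best, f1)
    return best


def random_instance(n, seed, n_ties=0):
    rng = np.random.default_rng(seed)
    scores = rng.random(n)
    if n_ties:
        scores[: n_ties] = np.round(scores[: n_ties], 1)  # force ties
    labels = (rng.random(n) < 0.35).astype(int)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    return scores, labels


# ---------------------------------------------------------------------------
# AUROC
# ---------------------------------------------------------------------------


class TestAuroc:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 0]) == 1.0

    def test_inverted_ranking(self):
        assert auroc([0.1, 0.9], [1, 0]) == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_concordance_oracle(self, seed):
        scores, labels = random_instance(200, seed, n_ties=40)
        assert abs(auroc(scores, labels) - auroc_by_pairwise_concordance(scores, labels)) < 1e-12

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestAveragePrecision:
    def test_all_positives_first(self):
        assert average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_last(self):
        n = 10
        scores = np.linspace(1.0, 0.1, n)
        labels = [0] * (n - 1) + [1]
        assert average_precision(scores, labels) == pytest.approx(1 / n)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_enumeration_oracle(self, seed):
        scores, labels = random_instance(200, seed, n_ties=40)
        assert abs(
            average_precision(scores, labels) - ap_by_threshold_enumeration(scores, labels)
        ) < 1e-12

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            average_precision([0.5, 0.4], [0, 0])


class TestF1Threshold:
    def test_perfect_separation(self):
        t, f1 = best_f1_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert f1 == 1.0 and 0.2 <= t < 0.8

    def test_all_equal_scores_closed_form(self):
        # all scores tie: the best call is everything-positive, whose F1 is
        # 2p/(p+1) at prevalence p
        labels = [1] * 3 + [0] * 7
        p = 0.3
        _, f1 = best_f1_threshold([0.5] * 10, labels)
        assert f1 == pytest.approx(2 * p / (p + 1))

    @pytest.mark.parametrize("seed", [6, 7, 8])
    def test_matches_exhaustive_oracle(self, seed):
        scores, labels = random_instance(100, seed, n_ties=30)
        _, f1 = best_f1_threshold(scores, labels)
        assert f1 == pytest.approx(f1_by_exhaustive_enumeration(scores, labels), abs=1e-12)

    def test_fold_wise_report_shapes(self):
        folds_s = [[0.9, 0.2, 0.8, 0.3], [0.7, 0.6, 0.2, 0.1]]
        folds_y = [[1, 0, 1, 0], [1, 1, 0, 0]]
        ts, f1s, cm = f1_with_fold_threshold(folds_s, folds_y)
        assert len(ts) == len(f1s) == 2
        assert cm.shape == (2, 2)
        assert cm.sum() == 4  # average of two 4-patient matrices

    def test_confusion_counts_sum_to_patients(self):
        cm = confusion_at_threshold([0.9, 0.4, 0.2], [1, 0, 1], 0.5)
        assert cm.sum() == 3
        assert cm[1, 1] == 1 and cm[1, 0] == 1 and cm[0, 0] == 1


class TestPairedFoldTest:
    def test_identical_inputs_flagged_degenerate(self):
        out = paired_fold_test([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert out["degenerate"] and math.isnan(out["p"])

    def test_matches_textbook_t_statistic(self):
        b = [0.70, 0.72, 0.69, 0.71, 0.70]
        d = [0.05, 0.06, 0.07, 0.05, 0.06]
        a = [bi + di for bi, di in zip(b, d)]
        out = paired_fold_test(a, b)
        dbar = np.mean(d)
        sd = np.std(d, ddof=1)
        t_hand = dbar / (sd / np.sqrt(len(d)))
        from scipy.stats import t as tdist

        p_hand = 2 * tdist.sf(abs(t_hand), df=len(d) - 1)
        assert out["t"] == pytest.approx(t_hand, abs=1e-10)
        assert out["p"] == pytest.approx(p_hand, abs=1e-10)

    def test_two_sided_symmetry(self):
        a = [0.8, 0.85, 0.9, 0.7]
        b = [0.75, 0.8, 0.95, 0.65]
        assert paired_fold_test(a, b)["p"] == pytest.approx(paired_fold_test(b, a)["p"])

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            paired_fold_test([0.5], [0.4])


class TestFeatureSummary:
    @staticmethod
    def _fixture():
        scores = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(8)],
                "p_msi": [0.9, 0.8, 0.2, 0.1, 0.7, 0.3, 0.6, 0.4],
            }
        )
        labels = {f"p{i}": y for i, y in enumerate([1, 1, 1, 0, 0, 0, 1, 0])}
        feats = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(8)],
                "snp_count": [5000, 3000, 200, 50, 80, 60, 2500, 90],
                "cnv_fraction": [0.001, 0.002, 0.004, 0.3, 0.2, 0.4, 0.003, 0.25],
                "cimp_category": ["CIMP-H"] * 4 + ["non-CIMP"] * 4,
            }
        )
        return scores, labels, feats

    def test_hand_computed_cells(self):
        scores, labels, feats = self._fixture()
        out = misclassification_feature_summary(
            scores, labels, threshold=0.5, patient_features=feats, level="patient"
        ).set_index("outcome")
        # TP: p0, p1, p6 (score>0.5, y=1); FN: p2; FP: p4, p7? p7 score 0.4 -> TN
        assert out.loc["TP", "n"] == 3
        assert out.loc["TP", "snp_count_median"] == 3000
        assert out.loc["FN", "n"] == 1
        assert out.loc["FN", "snp_count_median"] == 200
        assert out.loc["FP", "n"] == 1  # p4 at 0.7
        assert out.loc["TN", "n"] == 3
        assert out.loc["TP", "n_CIMP-H"] == 2  # p0, p1; p6 is non-CIMP

    def test_all_correct_leaves_no_error_cells(self):
        scores, labels, feats = self._fixture()
        scores = scores.copy()
        scores["p_msi"] = [0.9 if labels[p] else 0.1 for p in scores["patient_id"]]
        out = misclassification_feature_summary(
            scores, labels, 0.5, feats, level="patient"
        )
        assert set(out["outcome"]) == {"TP", "TN"}

    def test_unlabelled_patient_rejected(self):
        scores, labels, feats = self._fixture()
        del labels["p3"]
        with pytest.raises(ValueError, match="p3"):
            misclassification_feature_summary(scores, labels, 0.5, feats, level="patient")


class TestFeatureSummaryOnTrainedBaseline:
    def test_false_negatives_concentrate_at_low_snp(self):
        """On an SNP-coupled cohort the binary baseline's false-negative MSI
        patches must sit at markedly lower SNP counts than its true
        positives — the coupling signature that motivates decomposition."""
        from bpsubtype.aggregation import aggregate
        from bpsubtype.classifier import predict
        from bpsubtype.orchestration import (
            ExperimentConfig,
            _prepare_seed,
            _train_fold_pair,
        )
        from bpsubtype.sublabels import snp_scheme

        cfg = ExperimentConfig(scheme=snp_scheme(), seeds=[0])
        patients, _, images, sublab, balanced, folds, test_patches = _prepare_seed(cfg, 0)
        cache: dict = {}
        baseline, _ = _train_fold_pair(
            balanced, folds, 0, sublab, cfg.scheme, cfg.training, images, cache, 0
        )
        preds = predict(baseline, test_patches, images, cache)
        truth = {q.patient_id: 1 if q.base_label == "MSI" else 0 for q in test_patches}
        scores = aggregate(preds)
        y = np.array([truth[p] for p in scores["patient_id"]])
        threshold, _ = best_f1_threshold(scores["p_msi"].to_numpy(), y)
        feats = pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in patients],
                "snp_count": [p.snp_count for p in patients],
                "cnv_fraction": [p.cnv_fraction for p in patients],
                "cimp_category": [p.cimp_category for p in patients],
            }
        )
        table = misclassification_feature_summary(
            preds, truth, threshold, feats
        ).set_index("outcome")
        assert table.loc["FN", "snp_count_median"] < table.loc["TP", "snp_count_median"]
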