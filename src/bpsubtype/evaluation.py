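"""Patient-level performance metrics and fold-wise statistics.

AUROC (probability that a random MSI patient outranks a random MSS
patient, ties counted half), average precision (step-wise area under
the precision-recall curve), F1 with a data-driven decision threshold,
fold-wise paired t-tests, averaged confusion matrices, and the
misclassification-versus-molecular-feature breakdown.  MSI is the
positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

__all__ = [
    "MetricReport",
    "auroc",
    "average_precision",
    "f1_with_fold_threshold",
    "best_f1_threshold",
    "paired_fold_test",
    "confusion_at_threshold",
    "misclassification_feature_summary",
]


def _check_binary(labels: np.ndarray) -> None:
    u = set(np.unique(labels).tolist())
    if not u <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(u)}")
    if len(u) < 2:
        raise ValueError("both classes must be present")


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (trapezoidal; equals the pairwise
    concordance probability with ties counted 1/2)."""
    y = np.asarray(labels)
    _check_binary(y)
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Step-wise AP = sum over descending thresholds of (R_k - R_{k-1}) P_k."""
    y = np.asarray(labels)
    u = set(np.unique(y).tolist())
    if not u <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {sorted(u)}")
    if 1 not in u:
        raise ValueError("average precision needs at least one positive")
    return float(average_precision_score(y, np.asarray(scores, dtype=np.float64)))


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent sorted unique scores plus 0 and 1, and a
    below-minimum sentinel so the all-positive call stays reachable even
    when a score sits exactly at 0."""
    s = np.unique(scores)
    mids = (s[1:] + s[:-1]) / 2.0 if len(s) > 1 else np.empty(0)
    return np.unique(np.concatenate([[-np.inf, 0.0], mids, [1.0]]))


def best_f1_threshold(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """Sweep candidate thresholds; return (threshold, F1) maximizing F1,
    ties broken toward the lower threshold.  Calls are score > threshold."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    _check_binary(y)
    best_t, best_f1 = -np.inf, -1.0
    for t in _candidate_thresholds(s):
        f1 = f1_score(y, (s > t).astype(int), zero_division=0.0)
        if f1 > best_f1:
            best_t, best_f1 = float(t), float(f1)
    return best_t, best_f1


def f1_with_fold_threshold(
    fold_scores: Sequence[Sequence[float]],
    fold_labels: Sequence[Sequence[int]],
) -> tuple[list[float], list[float], np.ndarray]:
    """Per fold, pick the F1-maximizing threshold and report (thresholds,
    F1s, confusion matrix averaged across folds).  The averaged matrix is
    the mean of per-fold [[TN, FP], [FN, TP]] count matrices."""
    thresholds: list[float] = []
    f1s: list[float] = []
    mats = []
    for s, y in zip(fold_scores, fold_labels):
        t, f1 = best_f1_threshold(s, y)
        thresholds.append(t)
        f1s.append(f1)
        mats.append(confusion_at_threshold(s, y, t))
    return thresholds, f1s, np.mean(mats, axis=0)


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> np.ndarray:
    """2x2 counts [[TN, FP], [FN, TP]] calling MSI when score > threshold."""
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels)
    pred = (s > threshold).astype(int)
    return np.array(
        [
            [int(((y == 0) & (pred == 0)).sum()), int(((y == 0) & (pred == 1)).sum())],
            [int(((y == 1) & (pred == 0)).sum()), int(((y == 1) & (pred == 1)).sum())],
        ]
    )


def paired_fold_test(metric_a: Sequence[float], metric_b: Sequence[float]) -> dict:
    """Two-sided Student's paired t-test on per-fold metric differences.

    Returns {"t", "p", "degenerate"}; a zero-variance difference vector is
    flagged degenerate (p undefined) rather than silently reported as 0.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired metric lists must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two folds for a paired test")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return {"t": float("nan"), "p": float("nan"), "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "degenerate": False}


@dataclass
class MetricReport:
    """Fold-wise patient-level performance of one model."""

    auroc_per_fold: list[float]
    ap_per_fold: list[float]
    f1_per_fold: list[float]
    f1_thresholds: list[float]
    confusion_mean: np.ndarray
    paired_t_p: float | None = None  # vs a reference model, when computed
    extras: dict = field(default_factory=dict)

    @staticmethod
    def _ci(values: Sequence[float]) -> tuple[float, float, float, float]:
        v = np.asarray(values, dtype=np.float64)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        half = 1.96 * sd / np.sqrt(len(v)) if len(v) > 1 else 0.0
        return mean, sd, mean - half, mean + half

    def summary(self) -> dict:
        out: dict = {}
        for name, vals in (
            ("auroc", self.auroc_per_fold),
            ("ap", self.ap_per_fold),
            ("f1", self.f1_per_fold),
        ):
            mean, sd, lo, hi = self._ci(vals)
            out[name] = {
                "per_fold": list(map(float, vals)),
                "mean": mean,
                "sd": sd,
                "ci95": [lo, hi],
            }
        out["f1_thresholds"] = list(map(float, self.f1_thresholds))
        out["confusion_mean"] = np.asarray(self.confusion_mean).tolist()
        if self.paired_t_p is not None:
            out["paired_t_p"] = self.paired_t_p
        out.update(self.extras)
        return out

    @classmethod
    def from_folds(
        cls,
        fold_scores: Sequence[Sequence[float]],
        fold_labels: Sequence[Sequence[int]],
    ) -> "MetricReport":
        aurocs = [auroc(s, y) for s, y in zip(fold_scores, fold_labels)]
        aps = [average_precision(s, y) for s, y in zip(fold_scores, fold_labels)]
        ts, f1s, cm = f1_with_fold_threshold(fold_scores, fold_labels)
        return cls(
            auroc_per_fold=aurocs,
            ap_per_fold=aps,
            f1_per_fold=f1s,
            f1_thresholds=ts,
            confusion_mean=cm,
        )


def plot_roc_pr(scores, labels, out_path) -> None:
    """Minimal ROC + PR figure for one set of patient scores (PNG/PDF by
    file extension).  Requires matplotlib (the ``plot`` extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import precision_recall_curve, roc_curve

    y = np.asarray(labels)
    s = np.asarray(scores, dtype=np.float64)
    fpr, tpr, _ = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    ax1.plot(fpr, tpr)
    ax1.plot([0, 1], [0, 1], ls="--", c="gray", lw=0.8)
    ax1.set(xlabel="FPR", ylabel="TPR", title=f"ROC (AUROC {auroc(s, y):.3f})")
    ax2.plot(rec, prec)
    ax2.set(xlabel="Recall", ylabel="Precision",
            title=f"PR (AP {average_precision(s, y):.3f})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)


def misclassification_feature_summary(
    scores: pd.DataFrame,
    labels: Mapping[str, int],
    threshold: float,
    patient_features: pd.DataFrame,
    level: str = "patch",
) -> pd.DataFrame:
    """Molecular-feature breakdown by classification outcome.

    ``scores`` is either a PredictionTable (patch level, with class
    probability columns) or a PatientScoreTable; each unit is assigned
    TP/FP/TN/FN at ``threshold`` (MSI positive), then joined with the
    patient-level features.  Returns one row per outcome cell with
    quartiles of snp_count and cnv_fraction and counts per
    cimp_category; units missing features are flagged, not dropped.
    """
    from .aggregation import patch_msi_probabilities

    if level not in ("patch", "patient"):
        raise ValueError("level must be 'patch' or 'patient'")
    df = scores.copy()
    if level == "patch":
        df["p_msi"] = patch_msi_probabilities(df) if "p_msi" not in df else df["p_msi"]
    df["y"] = df["patient_id"].map(dict(labels))
    if df["y"].isna().any():
        missing = df.loc[df["y"].isna(), "patient_id"].unique()
        raise ValueError(f"no label for patients: {sorted(missing)[:5]}")
    pred = df["p_msi"] > threshold
    outcome = np.where(
        df["y"] == 1, np.where(pred, "TP", "FN"), np.where(pred, "FP", "TN")
    )
    df["outcome"] = outcome
    feats = patient_features.set_index("patient_id")
    joined = df.join(feats, on="patient_id", rsuffix="_feat")
    joined["feature_missing"] = joined["snp_count"].isna() | joined["cnv_fraction"].isna()

    rows = []
    for cell, grp in joined.groupby("outcome"):
        row: dict = {"outcome": cell, "n": len(grp), "n_missing_features": int(grp["feature_missing"].sum())}
        ok = grp[~grp["feature_missing"]]
        for feat in ("snp_count", "cnv_fraction"):
            qs = ok[feat].quantile([0.25, 0.5, 0.75]) if len(ok) else pd.Series([np.nan] * 3, index=[0.25, 0.5, 0.75])
            row[f"{feat}_q25"] = float(qs.loc[0.25]) if len(ok) else np.nan
            row[f"{feat}_median"] = float(qs.loc[0.5]) if len(ok) else np.nan
            row[f"{feat}_q75"] = float(qs.loc[0.75]) if len(ok) else np.nan
        for cat in ("CIMP-H", "CIMP-L", "non-CIMP"):
            row[f"n_{cat}"] = int((ok["cimp_category"] == cat).sum())
        rows.append(row)
    return pd.DataFrame(rows).sort_values("outcome").reset_index(drop=True)
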