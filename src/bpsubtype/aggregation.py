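"""Patch probabilities -> patient-level MSI scores, and two-model fusion.

A patient's MSI score is the arithmetic mean of their per-patch MSI
probabilities.  For a three-class decomposed model, a patch's MSI
probability is the *maximum* of its two MSI sub-class probabilities,
taken per patch before any averaging.  Two decomposed models can be
fused patch-wise by a small MLP over the concatenated 6-vector of class
probabilities; the constituents stay frozen, and the fusion consumes
probabilities only — never images, labels or genomic covariates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._nn import SoftmaxNet

__all__ = [
    "patch_msi_probability",
    "patch_msi_probabilities",
    "aggregate_patient",
    "aggregate",
    "patient_scores",
    "FusionModel",
    "train_fusion",
    "combine_predict",
]

META_COLS = ("patch_id", "patient_id")


def class_columns(preds: pd.DataFrame) -> list[str]:
    return [c for c in preds.columns if c not in META_COLS]


def _msi_columns(class_names: Sequence[str]) -> list[str]:
    msi = [c for c in class_names if c != "MSS"]
    if not msi or "MSS" not in class_names:
        raise ValueError(f"unrecognized class layout: {list(class_names)}")
    if len(msi) not in (1, 2):
        raise ValueError(f"expected 1 or 2 MSI (sub-)classes, got {msi}")
    return msi


def patch_msi_probability(row: Mapping[str, float], class_names: Sequence[str]) -> float:
    """MSI probability of one patch: the MSI entry for a binary model, the
    max over the two MSI sub-class entries for a three-class model."""
    msi = _msi_columns(class_names)
    return float(max(row[c] for c in msi))


def patch_msi_probabilities(preds: pd.DataFrame) -> pd.Series:
    """Vectorized per-patch MSI probability for a PredictionTable."""
    msi = _msi_columns(class_columns(preds))
    return preds[msi].max(axis=1)


def aggregate_patient(probs: Sequence[float], patient_id: str = "?") -> float:
    """Mean of a patient's per-patch MSI probabilities."""
    arr = np.asarray(list(probs), dtype=np.float64)
    if arr.size == 0:
        raise ValueError(f"patient {patient_id} has no patches to aggregate")
    return float(arr.mean())


def aggregate(preds: pd.DataFrame) -> pd.DataFrame:
    """PredictionTable -> PatientScoreTable (patient_id, p_msi)."""
    p = patch_msi_probabilities(preds)
    out = (
        pd.DataFrame({"patient_id": preds["patient_id"], "p_msi": p})
        .groupby("patient_id", sort=True)["p_msi"]
        .mean()
        .reset_index()
    )
    return out


def patient_scores(
    patch_patient_ids: Sequence[tuple[str, str]],
    probs: np.ndarray,
    class_names: Sequence[str],
) -> pd.Series:
    """Array-level fast path used inside training loops: per-patient mean
    of max-over-MSI-subclass patch probabilities."""
    names = list(class_names)
    msi_idx = [names.index(c) for c in _msi_columns(names)]
    p = probs[:, msi_idx].max(axis=1)
    pid = pd.Series([pp for _, pp in patch_patient_ids], name="patient_id")
    return pd.Series(p).groupby(pid).mean()


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------


@dataclass
class FusionModel:
    """MLP over the concatenated class probabilities of two frozen models."""

    net: SoftmaxNet
    input_columns: list[str]  # A's classes then B's classes, prefixed a_/b_
    class_names: tuple[str, str] = ("MSS", "MSI")

    def predict_proba(self, X6: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(X6)


def _aligned_matrix(
    preds_A: pd.DataFrame, preds_B: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Align the two tables by patch_id and build the 6-column input."""
    ids_a, ids_b = set(preds_A["patch_id"]), set(preds_B["patch_id"])
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise ValueError(f"patch sets differ between models: {diff[:10]}")
    a = preds_A.sort_values("patch_id").reset_index(drop=True)
    b = preds_B.sort_values("patch_id").reset_index(drop=True)
    ca, cb = class_columns(a), class_columns(b)
    if len(ca) != 3 or len(cb) != 3:
        raise ValueError("fusion expects two 3-class prediction tables")
    X = np.concatenate([a[ca].to_numpy(), b[cb].to_numpy()], axis=1)
    cols = [f"a_{c}" for c in ca] + [f"b_{c}" for c in cb]
    return a, X, cols


def train_fusion(
    preds_A: pd.DataFrame,
    preds_B: pd.DataFrame,
    labels: Mapping[str, str],
    hidden: int = 16,
    epochs: int = 50,
    lr: float = 1e-3,
    batch_size: int = 256,
    seed: int = 0,
) -> FusionModel:
    """Train the fusion MLP on patch-level binary labels.

    ``labels`` maps patch_id -> base label (MSI/MSS).  The constituent
    models are never touched — only their emitted probabilities are used.
    """
    meta, X, cols = _aligned_matrix(preds_A, preds_B)
    y = np.array([1 if labels[pid] == "MSI" else 0 for pid in meta["patch_id"]])
    if len(set(y.tolist())) < 2:
        raise ValueError("fusion training needs both MSI and MSS patches")
    net = SoftmaxNet(X.shape[1], 2, hidden=(hidden,), seed=seed)
    net.fit(
        X, y,
        epochs=epochs, batch_size=batch_size, lr=lr,
        rng=np.random.default_rng(seed + 1),
    )
    return FusionModel(net=net, input_columns=cols)


def combine_predict(
    preds_A: pd.DataFrame,
    preds_B: pd.DataFrame,
    fusion_model: FusionModel | Callable[[np.ndarray], np.ndarray],
) -> pd.DataFrame:
    """Apply a fusion model patch-wise: 6-vector in, binary (MSS, MSI)
    probabilities out, aligned by patch_id (order-independent)."""
    meta, X, _ = _aligned_matrix(preds_A, preds_B)
    if isinstance(fusion_model, FusionModel):
        probs = fusion_model.predict_proba(X)
    else:
        probs = np.asarray(fusion_model(X))
    out = meta[["patch_id", "patient_id"]].copy()
    out["MSS"] = probs[:, 0]
    out["MSI"] = probs[:, 1]
    return out
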