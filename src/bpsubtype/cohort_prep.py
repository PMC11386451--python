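"""Balanced, stratified training material.

Three mechanisms, applied in this order when building an experiment:
patch-level class balancing by randomly discarding majority-class
patches (done once, at cohort construction), patient-level stratified
k-folds keyed on the sub-labels, and reciprocal-count sampling weights
for drawing balanced minibatches during training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .synthetic_cohort import PatchRecord, PatientRecord

__all__ = ["FoldAssignment", "balance_patches", "stratified_folds", "sampling_weights"]


@dataclass
class FoldAssignment:
    k: int
    assignment: Mapping[str, int]  # patient_id -> fold index in [0, k)

    def patients_in_fold(self, fold: int) -> list[str]:
        return [pid for pid, f in self.assignment.items() if f == fold]

    def patients_not_in_fold(self, fold: int) -> list[str]:
        return [pid for pid, f in self.assignment.items() if f != fold]


def balance_patches(
    patches: Sequence[PatchRecord],
    labels: Mapping[str, str],
    rng: np.random.Generator,
) -> list[PatchRecord]:
    """Discard majority-class patches uniformly at random until the two
    base classes have equal patch counts.  The minority class is never
    touched; relative order of surviving patches is preserved."""
    classes = sorted({labels[p.patch_id] for p in patches})
    if len(classes) < 2:
        raise ValueError(f"balancing needs two classes, got {classes}")
    if len(classes) > 2:
        raise ValueError(f"balancing is defined for two base classes, got {classes}")
    by_class = {c: [p for p in patches if labels[p.patch_id] == c] for c in classes}
    counts = {c: len(v) for c, v in by_class.items()}
    minority = min(classes, key=lambda c: counts[c])
    majority = max(classes, key=lambda c: counts[c])
    if counts[minority] == counts[majority]:
        return list(patches)
    keep_idx = rng.choice(counts[majority], size=counts[minority], replace=False)
    keep_ids = {by_class[majority][i].patch_id for i in keep_idx}
    return [
        p
        for p in patches
        if labels[p.patch_id] == minority or p.patch_id in keep_ids
    ]


def stratified_folds(
    patients: Sequence[PatientRecord],
    strat_key: Mapping[str, str],
    k: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Patient-level stratified k-fold partition keyed on ``strat_key``
    (typically the sub-labels), so every fold sees a near-identical mix
    of classes and their internal genomic sub-classes.

    Patients are sorted by id before splitting, making the assignment
    invariant to input ordering for a fixed seed.  Strata smaller than k
    are handled by scikit-learn's stratified splitter (with a warning).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the number of patients ({len(patients)})")
    ordered = sorted(patients, key=lambda p: p.patient_id)
    ids = [p.patient_id for p in ordered]
    y = [strat_key[pid] for pid in ids]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(ids)), y)):
        for i in test_idx:
            assignment[ids[i]] = fold
    return FoldAssignment(k=k, assignment=assignment)


def sampling_weights(
    patches: Sequence[PatchRecord], labels: Mapping[str, str]
) -> np.ndarray:
    """Weight of a patch = 1 / (count of its class), so weighted sampling
    with replacement draws each class with equal expected frequency."""
    lab = [labels[p.patch_id] for p in patches]
    counts: dict[str, int] = {}
    for l in lab:
        counts[l] = counts.get(l, 0) + 1
    if any(v == 0 for v in counts.values()) or not counts:
        raise ValueError("every class must have at least one patch")
    return np.array([1.0 / counts[l] for l in lab], dtype=np.float64)
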