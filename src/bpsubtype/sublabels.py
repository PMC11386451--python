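"""Decomposition of the MSI class into genomically-defined sub-classes.

The training trick at the heart of the pipeline: instead of a binary
MSI/MSS target, MSI patients are relabelled into two sub-classes by a
genomic covariate — a numeric threshold rule for SNP count or CNV
fraction (strictly greater than the threshold -> the "high" sub-class),
or a categorical rule for CIMP status (CIMP-H vs everything else).
MSS patients are never relabelled.  Inference still uses images only;
the covariate enters the model solely through the training labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import yaml

from .synthetic_cohort import PatientRecord

__all__ = [
    "SubLabelScheme",
    "SweepResult",
    "assign_sublabels",
    "apply_training_exclusion",
    "sweep_threshold",
    "snp_scheme",
    "cimp_scheme",
    "cnv_scheme",
    "DEFAULT_SNP_SWEEP_GRID",
]

logger = logging.getLogger(__name__)

#: default candidate thresholds for the SNP sweep, 800..1500 step 100
DEFAULT_SNP_SWEEP_GRID: tuple[float, ...] = tuple(float(t) for t in range(800, 1501, 100))

#: default CNV decision point, from qualitative evaluation of the CNV split
DEFAULT_CNV_THRESHOLD: float = 0.005


@dataclass
class SubLabelScheme:
    """A rule mapping MSI patients to one of two sub-class labels.

    ``threshold`` rules: covariate strictly greater than ``threshold``
    -> ``high_class_name``, otherwise ``low_class_name`` (a value equal
    to the threshold goes to the low class).  ``category`` rules split
    on CIMP-H membership.  ``exclude_mss_cimp_h`` removes CIMP-H MSS
    patients from *training* data only — never from test data.
    """

    feature: str  # snp | cimp | cnv
    rule_kind: str = "threshold"  # threshold | category
    threshold: float | None = None
    high_class_name: str = "MSI2"
    low_class_name: str = "MSI1"
    exclude_mss_cimp_h: bool = False

    def __post_init__(self) -> None:
        if self.feature not in ("snp", "cimp", "cnv"):
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.rule_kind not in ("threshold", "category"):
            raise ValueError(f"unknown rule_kind {self.rule_kind!r}")
        if self.rule_kind == "threshold":
            if self.threshold is None or not float("-inf") < float(self.threshold) < float("inf"):
                raise ValueError("threshold rules need a finite threshold")
        if self.high_class_name == self.low_class_name:
            raise ValueError("sub-class names must be distinct")

    # -- serialization ------------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "feature": self.feature,
                "rule_kind": self.rule_kind,
                "threshold": self.threshold,
                "high_class_name": self.high_class_name,
                "low_class_name": self.low_class_name,
                "exclude_mss_cimp_h": self.exclude_mss_cimp_h,
            }
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SubLabelScheme":
        return cls(**yaml.safe_load(text))

    @property
    def class_names(self) -> list[str]:
        """Ordered 3-class label layout: MSS first, then low, then high."""
        return ["MSS", self.low_class_name, self.high_class_name]


def snp_scheme(threshold: float = 1200.0) -> SubLabelScheme:
    """SNP-count split; 1200 is the sweep optimum on the original cohort."""
    return SubLabelScheme(feature="snp", rule_kind="threshold", threshold=threshold)


def cimp_scheme(exclude_mss_cimp_h: bool = True) -> SubLabelScheme:
    return SubLabelScheme(
        feature="cimp",
        rule_kind="category",
        high_class_name="MSI-CIMP-H",
        low_class_name="MSI-NON-CIMP-H",
        exclude_mss_cimp_h=exclude_mss_cimp_h,
    )


def cnv_scheme(threshold: float = DEFAULT_CNV_THRESHOLD) -> SubLabelScheme:
    return SubLabelScheme(feature="cnv", rule_kind="threshold", threshold=threshold)


def _feature_value(patient: PatientRecord, feature: str):
    if feature == "snp":
        return patient.snp_count
    if feature == "cnv":
        return patient.cnv_fraction
    return patient.cimp_category


def assign_sublabels(
    patients: Iterable[PatientRecord], scheme: SubLabelScheme
) -> dict[str, str]:
    """Map each patient to a sub-label: MSS stays MSS; MSI goes to the
    high sub-class iff its covariate is strictly above the threshold
    (or is CIMP-H for the categorical rule)."""
    out: dict[str, str] = {}
    for p in patients:
        if p.subtype == "MSS":
            out[p.patient_id] = "MSS"
            continue
        value = _feature_value(p, scheme.feature)
        if value is None or (isinstance(value, float) and value != value):
            raise ValueError(
                f"patient {p.patient_id} has no value for feature {scheme.feature!r}"
            )
        if scheme.rule_kind == "category":
            is_high = value == "CIMP-H"
        else:
            is_high = float(value) > float(scheme.threshold)
        out[p.patient_id] = scheme.high_class_name if is_high else scheme.low_class_name
    return out


def apply_training_exclusion(
    patients: Sequence[PatientRecord], scheme: SubLabelScheme
) -> list[PatientRecord]:
    """Drop training-split MSS patients with CIMP-H when the scheme asks
    for it.  Test patients and MSI patients are always retained."""
    if not scheme.exclude_mss_cimp_h:
        return list(patients)
    return [
        p
        for p in patients
        if not (p.split == "train" and p.subtype == "MSS" and p.cimp_category == "CIMP-H")
    ]


@dataclass
class SweepResult:
    candidate_thresholds: list[float]
    validation_auroc_per_candidate: list[float]
    selected_threshold: float
    skipped: list[float] = field(default_factory=list)


def sweep_threshold(
    candidates: Sequence[float],
    train_patients: Sequence[PatientRecord],
    val_patients: Sequence[PatientRecord],
    trainer: Callable[[dict[str, str], Sequence[PatientRecord], Sequence[PatientRecord]], float],
    feature: str = "snp",
) -> SweepResult:
    """Select the sub-class threshold maximizing validation AUROC.

    ``trainer(sublabels, train_patients, val_patients) -> auroc`` is the
    training contract: it receives the candidate-specific sub-labels,
    trains however it likes, and reports patient-level validation AUROC.
    Candidates that empty one MSI sub-class in training are skipped with
    a warning.  Ties break toward the smallest threshold.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if len({p.subtype for p in val_patients}) < 2:
        raise ValueError("validation fold must contain both classes")
    kept: list[float] = []
    aurocs: list[float] = []
    skipped: list[float] = []
    for t in candidates:
        scheme = SubLabelScheme(feature=feature, rule_kind="threshold", threshold=float(t))
        labels = assign_sublabels(list(train_patients) + list(val_patients), scheme)
        train_subs = {labels[p.patient_id] for p in train_patients if p.subtype == "MSI"}
        if len(train_subs) < 2:
            logger.warning("threshold %s empties one MSI sub-class in training; skipped", t)
            skipped.append(float(t))
            continue
        kept.append(float(t))
        aurocs.append(float(trainer(labels, train_patients, val_patients)))
    if not kept:
        raise ValueError("every candidate threshold emptied an MSI sub-class")
    best = max(range(len(kept)), key=lambda i: (aurocs[i], -kept[i]))
    return SweepResult(
        candidate_thresholds=kept,
        validation_auroc_per_candidate=aurocs,
        selected_threshold=kept[best],
        skipped=skipped,
    )
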