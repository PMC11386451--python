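"""Patch-level classifiers: binary baseline and three-class decomposed head.

The backbone is a lightweight convolutional featurizer with fixed,
seeded random filters (one 5x5 conv layer, ReLU, 3x3 spatial average
pooling, plus per-channel colour statistics); only the softmax head is
trained, with Adam on cross-entropy and a weighted random sampler for
class balance.  The baseline and the decomposed ("biologically-primed")
model differ *only* in the width of that head — two vs three classes —
everything else (features, optimizer, schedule, sampler) is identical,
which is what makes the comparison between them a test of label
decomposition rather than of capacity.

Model selection: after every epoch the patient-level MSI-vs-MSS AUROC
on the validation patients is computed (max-over-subclass rule, then
per-patient mean), and the epoch checkpoint with the highest value is
returned.

An ``inception_v3_finetune`` backbone name is reserved as an adapter
hook for full-scale transfer-learning runs; it is not implemented here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, MutableMapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._nn import SoftmaxNet
from .cohort_prep import sampling_weights
from .synthetic_cohort import PatchRecord, load_image

__all__ = ["TrainingConfig", "TrainedModel", "extract_features", "train", "predict"]

_KERNEL = 5
_STRIDE = 2
_POOL_GRID = 3


@dataclass
class TrainingConfig:
    backbone: str = "small_convnet"
    n_classes: int = 2
    learning_rate: float = 1e-3
    epochs: int = 15
    batch_size: int = 64
    seed: int = 0
    n_filters: int = 32
    backbone_seed: int = 0  # filters are deterministic in this alone

    def __post_init__(self) -> None:
        if self.backbone not in ("small_convnet", "inception_v3_finetune"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _filters(n_filters: int, backbone_seed: int) -> np.ndarray:
    """Fixed random filter bank, shape (k*k*3, n_filters), zero-mean and
    unit-norm per filter."""
    rng = np.random.default_rng(backbone_seed)
    f = rng.normal(size=(_KERNEL * _KERNEL * 3, n_filters))
    f -= f.mean(axis=0, keepdims=True)
    f /= np.linalg.norm(f, axis=0, keepdims=True)
    return f


def _featurize_batch(imgs: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """(N, S, S, 3) uint8 -> (N, n_filters*9 + 6) features."""
    x = imgs.astype(np.float64) / 255.0 - 0.5
    win = sliding_window_view(x, (_KERNEL, _KERNEL), axis=(1, 2))
    win = win[:, ::_STRIDE, ::_STRIDE]  # (N, P, P, 3, k, k)
    n, p = win.shape[0], win.shape[1]
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, p * p, -1)
    resp = np.maximum(cols @ filt, 0.0).reshape(n, p, p, filt.shape[1])
    # 3x3 average-pool grid (trailing rows/cols beyond a multiple of 3 dropped)
    g = (p // _POOL_GRID) * _POOL_GRID
    pooled = (
        resp[:, :g, :g]
        .reshape(n, _POOL_GRID, g // _POOL_GRID, _POOL_GRID, g // _POOL_GRID, -1)
        .mean(axis=(2, 4))
        .reshape(n, -1)
    )
    color = np.concatenate([x.mean(axis=(1, 2)), x.std(axis=(1, 2))], axis=1)
    return np.concatenate([pooled, color], axis=1)


def extract_features(
    patches: Sequence[PatchRecord],
    images: Mapping[str, np.ndarray] | None = None,
    n_filters: int = 32,
    backbone_seed: int = 0,
    cache: MutableMapping[str, np.ndarray] | None = None,
    chunk: int = 256,
) -> np.ndarray:
    """Featurize patches (loading images by reference), with an optional
    per-patch cache shared across models that use the same backbone."""
    filt = _filters(n_filters, backbone_seed)
    out: dict[str, np.ndarray] = {}
    todo = [q for q in patches if cache is None or q.patch_id not in cache]
    for start in range(0, len(todo), chunk):
        block = todo[start : start + chunk]
        try:
            arrs = np.stack([load_image(q.image_ref, images) for q in block])
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"while featurizing patches: {exc}") from exc
        feats = _featurize_batch(arrs, filt)
        for q, f in zip(block, feats):
            out[q.patch_id] = f
            if cache is not None:
                cache[q.patch_id] = f
    if cache is not None:
        return np.stack([cache[q.patch_id] for q in patches])
    return np.stack([out[q.patch_id] for q in patches])


@dataclass
class TrainedModel:
    config: TrainingConfig
    class_names: list[str]
    head_params: list[np.ndarray]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    best_val_auroc: float
    best_epoch: int = -1

    def head(self) -> SoftmaxNet:
        net = SoftmaxNet(len(self.feature_mean), len(self.class_names))
        net.set_params(self.head_params)
        return net

    # -- persistence --------------------------------------------------------
    def save(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(
            out_dir / "weights.npz",
            feature_mean=self.feature_mean,
            feature_std=self.feature_std,
            **{f"param_{i}": p for i, p in enumerate(self.head_params)},
        )
        sidecar = {
            "config": asdict(self.config),
            "class_names": self.class_names,
            "best_val_auroc": self.best_val_auroc,
            "best_epoch": self.best_epoch,
            "n_params": len(self.head_params),
        }
        (out_dir / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "TrainedModel":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "model.json").read_text())
        data = np.load(in_dir / "weights.npz")
        return cls(
            config=TrainingConfig(**meta["config"]),
            class_names=list(meta["class_names"]),
            head_params=[data[f"param_{i}"] for i in range(meta["n_params"])],
            feature_mean=data["feature_mean"],
            feature_std=data["feature_std"],
            best_val_auroc=float(meta["best_val_auroc"]),
            best_epoch=int(meta["best_epoch"]),
        )


def _order_class_names(label_set: set[str]) -> list[str]:
    """MSS first, then the MSI (sub-)classes in sorted order."""
    rest = sorted(label_set - {"MSS"})
    return (["MSS"] if "MSS" in label_set else []) + rest


def train(
    train_patches: Sequence[PatchRecord],
    val_patches: Sequence[PatchRecord],
    labels: Mapping[str, str],
    config: TrainingConfig,
    images: Mapping[str, np.ndarray] | None = None,
    feature_cache: MutableMapping[str, np.ndarray] | None = None,
    class_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Train a patch classifier and return the checkpoint with the best
    patient-level validation AUROC.

    ``labels`` maps patch_id to its training label (base labels for the
    baseline, sub-labels for the decomposed model).  Validation AUROC is
    always the *binary* MSI-vs-MSS discrimination of the aggregated
    patient scores, regardless of head width.
    """
    from .aggregation import patient_scores  # local import to avoid a cycle
    from .evaluation import auroc

    if config.backbone == "inception_v3_finetune":
        raise NotImplementedError(
            "the inception_v3_finetune adapter is a hook for full-scale "
            "transfer-learning runs and is not trainable in this package"
        )
    if class_names is None:
        class_names = _order_class_names({labels[q.patch_id] for q in train_patches})
    class_names = list(class_names)
    if len(class_names) != config.n_classes:
        raise ValueError(
            f"config.n_classes={config.n_classes} but training labels "
            f"define {len(class_names)} classes: {class_names}"
        )
    idx_of = {c: i for i, c in enumerate(class_names)}
    y_train = np.array([idx_of[labels[q.patch_id]] for q in train_patches])
    if len(set(y_train.tolist())) < config.n_classes:
        raise ValueError("every class must be present in the training patches")

    X_train = extract_features(
        train_patches, images, config.n_filters, config.backbone_seed, feature_cache
    )
    X_val = extract_features(
        val_patches, images, config.n_filters, config.backbone_seed, feature_cache
    )
    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    std[std < 1e-9] = 1.0
    X_train = (X_train - mean) / std
    X_val = (X_val - mean) / std

    weights = sampling_weights(train_patches, labels)
    net = SoftmaxNet(X_train.shape[1], config.n_classes, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)

    val_ids = [(q.patch_id, q.patient_id) for q in val_patches]
    val_truth = {
        q.patient_id: 1 if q.base_label == "MSI" else 0 for q in val_patches
    }
    best = {"auroc": -np.inf, "epoch": -1, "params": net.get_params()}

    def on_epoch_end(epoch: int, model: SoftmaxNet) -> None:
        probs = model.predict_proba(X_val)
        scores = patient_scores(val_ids, probs, class_names)
        y = np.array([val_truth[pid] for pid in scores.index])
        a = auroc(scores.to_numpy(), y)
        if a > best["auroc"]:
            best.update(auroc=a, epoch=epoch, params=model.get_params())

    if len(set(val_truth.values())) < 2:
        raise ValueError("validation patients must include both MSI and MSS")

    net.fit(
        X_train,
        y_train,
        epochs=config.epochs,
        batch_size=config.batch_size,
        lr=config.learning_rate,
        sample_weights=weights,
        rng=rng,
        on_epoch_end=on_epoch_end,
    )
    return TrainedModel(
        config=config,
        class_names=class_names,
        head_params=best["params"],
        feature_mean=mean,
        feature_std=std,
        best_val_auroc=float(best["auroc"]),
        best_epoch=int(best["epoch"]),
    )


def predict(
    model: TrainedModel,
    patches: Sequence[PatchRecord],
    images: Mapping[str, np.ndarray] | None = None,
    feature_cache: MutableMapping[str, np.ndarray] | None = None,
):
    """Per-patch class probabilities as a PredictionTable DataFrame
    (columns: patch_id, patient_id, then one column per class).  Uses
    images only — no genomic covariates enter inference."""
    import pandas as pd

    X = extract_features(
        patches, images, model.config.n_filters, model.config.backbone_seed, feature_cache
    )
    X = (X - model.feature_mean) / model.feature_std
    probs = model.head().predict_proba(X)
    out = pd.DataFrame(
        {
            "patch_id": [q.patch_id for q in patches],
            "patient_id": [q.patient_id for q in patches],
        }
    )
    for i, c in enumerate(model.class_names):
        out[c] = probs[:, i]
    return out
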