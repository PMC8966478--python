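"""The task classifier: a small from-scratch CNN over masked activation maps.

Architecture family: five convolution layers for feature extraction followed
by two fully connected layers for K-way classification, trained with SGD on
categorical crossentropy (batch size 10, learning rate 1e-4 by default) with
optional stratified k-fold crossvalidation reporting.  This is the black box
whose decisions the counterfactual machinery explains; during GAN training
its parameters are frozen.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import nn
from .data import ActivationMap, LabeledDataset

__all__ = [
    "ClassifierConfig",
    "TaskClassifier",
    "ConfusionMatrix",
    "build_classifier",
    "train_classifier",
    "stratified_folds",
    "evaluate_confusion",
    "save_classifier",
    "load_classifier",
    "save_history_csv",
]


@dataclass
class ClassifierConfig:
    """Architecture and training hyperparameters for the task classifier."""

    input_shape: tuple[int, int] = (32, 64)
    conv_blocks: list[tuple[int, int, int]] = field(
        default_factory=lambda: [(8, 3, 2), (16, 3, 2), (16, 3, 2), (32, 3, 2), (32, 3, 2)]
    )
    fc_widths: list[int] = field(default_factory=lambda: [64])
    K: int = 7
    # From-scratch training needs a far larger SGD step than a fine-tuned
    # pretrained backbone would; 1e-4 barely moves a freshly initialized net.
    lr: float = 0.05
    batch_size: int = 10
    epochs: int = 50
    optimizer: str = "sgd"
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if min(self.lr, self.batch_size, self.epochs) <= 0:
            raise ValueError("lr, batch_size and epochs must be positive")


class TaskClassifier(nn.Module):
    """CNN emitting a K-class probability vector per map."""

    def __init__(self, cfg: ClassifierConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        h, w = cfg.input_shape
        layers: list[nn.Module] = []
        in_ch = 1
        for out_ch, kernel, stride in cfg.conv_blocks:
            layers.append(nn.Conv2d(in_ch, out_ch, kernel, rng,
                                    stride=stride, padding=kernel // 2))
            layers.append(nn.ReLU())
            h = (h + 2 * (kernel // 2) - kernel) // stride + 1
            w = (w + 2 * (kernel // 2) - kernel) // stride + 1
            if h < 1 or w < 1:
                raise ValueError("conv stack reduces the input below 1x1")
            in_ch = out_ch
        layers.append(nn.Flatten())
        width = in_ch * h * w
        for fc in cfg.fc_widths:
            layers.append(nn.Linear(width, fc, rng))
            layers.append(nn.ReLU())
            width = fc
        head = nn.Linear(width, cfg.K, rng)
        head.w.data *= 0.01  # near-uniform initial class probabilities
        layers.append(head)
        self.net = nn.Sequential(*layers)

    # -- forward ----------------------------------------------------------
    def logits(self, x: nn.Tensor) -> nn.Tensor:
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != tuple(self.cfg.input_shape):
            raise ValueError(
                f"expected input (N, 1, {self.cfg.input_shape[0]}, "
                f"{self.cfg.input_shape[1]}), got {x.shape}"
            )
        return self.net(x)

    def log_probs(self, x: nn.Tensor) -> nn.Tensor:
        return nn.log_softmax(self.logits(x), axis=1)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.log_probs(x).exp()

    # -- numpy-facing prediction API --------------------------------------
    def _to_batch(self, maps) -> np.ndarray:
        if isinstance(maps, ActivationMap):
            maps = [maps]
        if isinstance(maps, LabeledDataset):
            arr = maps.values_array()
        elif isinstance(maps, np.ndarray):
            arr = maps if maps.ndim == 3 else maps[None]
        else:
            arr = np.stack([m.values for m in maps])
        return arr[:, None].astype(np.float32)

    def predict_proba(self, maps) -> np.ndarray:
        with nn.no_grad():
            p = self.forward(nn.Tensor(self._to_batch(maps))).data
        return p.astype(np.float64)

    def predict(self, maps) -> np.ndarray:
        """Argmax class per map; exact ties resolve to the lowest class index."""
        return np.argmax(self.predict_proba(maps), axis=1)


def build_classifier(cfg: ClassifierConfig) -> TaskClassifier:
    return TaskClassifier(cfg)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # rows = true class, columns = assigned class
    class_names: list[str]

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["true\\assigned"] + self.class_names)
            for name, row in zip(self.class_names, self.counts):
                writer.writerow([name] + [int(v) for v in row])


def evaluate_confusion(clf: TaskClassifier, ds: LabeledDataset) -> ConfusionMatrix:
    labels = ds.labels_array()
    if np.any(labels < 0):
        raise ValueError("dataset contains unlabeled maps")
    pred = clf.predict(ds)
    counts = np.zeros((clf.cfg.K, clf.cfg.K), dtype=np.int64)
    np.add.at(counts, (labels, pred), 1)
    return ConfusionMatrix(counts, ds.class_names)


def stratified_folds(labels: np.ndarray, n_folds: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Disjoint, exhaustive, label-stratified fold index sets."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.sort(np.array(f, dtype=np.int64)) for f in folds]


def _crossentropy_batch(clf: TaskClassifier, x: np.ndarray,
                        y: np.ndarray) -> tuple[nn.Tensor, np.ndarray]:
    logp = clf.log_probs(nn.Tensor(x))
    n = x.shape[0]
    picked = logp[np.arange(n), y]
    loss = -picked.mean()
    pred = np.argmax(logp.data, axis=1)
    return loss, pred


def _run_epochs(clf: TaskClassifier, train: LabeledDataset, cfg: ClassifierConfig,
                rng: np.random.Generator, val: Optional[LabeledDataset],
                fold: int, history: list[dict]) -> None:
    x_all = train.values_array()[:, None].astype(np.float32)
    y_all = train.labels_array()
    opt = nn.SGD(clf.parameters(), lr=cfg.lr)
    n = len(train)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, pred = _crossentropy_batch(clf, x_all[idx], y_all[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            correct += int((pred == y_all[idx]).sum())
        rec = {
            "fold": fold,
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "train_acc": correct / n,
        }
        if val is not None and len(val):
            vy = val.labels_array()
            with nn.no_grad():
                vloss, vpred = _crossentropy_batch(
                    clf, val.values_array()[:, None].astype(np.float32), vy
                )
            rec["val_loss"] = vloss.item()
            rec["val_acc"] = float((vpred == vy).mean())
        history.append(rec)


def train_classifier(
    clf: TaskClassifier,
    ds: LabeledDataset,
    cfg: ClassifierConfig,
    crossvalidate: bool = False,
) -> tuple[TaskClassifier, list[dict]]:
    """Train by SGD on categorical crossentropy.

    With ``crossvalidate=True`` and ``cfg.folds >= 2``, first runs stratified
    k-fold crossvalidation (fresh model per fold, seeded from ``cfg.seed``)
    for reporting, then trains ``clf`` on the full ``ds``.  History rows carry
    the fold index; the final full-data fit is recorded as fold -1.
    """
    if len(ds) == 0:
        raise ValueError("cannot train on an empty dataset")
    labels = ds.labels_array()
    if np.any(labels < 0):
        raise ValueError("dataset contains unlabeled maps")
    if np.unique(labels).size < 2:
        raise ValueError("single-class dataset: nothing to discriminate")

    history: list[dict] = []
    if crossvalidate:
        if cfg.folds < 2:
            raise ValueError("crossvalidation requires folds >= 2")
        fold_rng = np.random.default_rng(cfg.seed)
        folds = stratified_folds(labels, cfg.folds, fold_rng)
        for f, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(len(ds)), val_idx)
            fold_cfg = ClassifierConfig(**{**asdict(cfg), "seed": cfg.seed + 1 + f})
            fold_clf = TaskClassifier(fold_cfg)
            _run_epochs(fold_clf, ds.subset(train_idx), cfg,
                        np.random.default_rng(cfg.seed + 1000 + f),
                        ds.subset(val_idx), f, history)
    _run_epochs(clf, ds, cfg, np.random.default_rng(cfg.seed), None, -1, history)
    return clf, history


def save_history_csv(history: Sequence[dict], path) -> None:
    keys = ["fold", "epoch", "train_loss", "train_acc", "val_loss", "val_acc"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        for row in history:
            writer.writerow({k: row.get(k, "") for k in keys})


def save_classifier(clf: TaskClassifier, path) -> None:
    """Self-describing checkpoint: config JSON + parameter arrays."""
    cfg_json = json.dumps(asdict(clf.cfg))
    np.savez(path, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             **clf.state_dict())


def load_classifier(path) -> TaskClassifier:
    with np.load(path) as z:
        cfg_dict = json.loads(bytes(z["__config__"]).decode())
        state = {k: z[k] for k in z.files if k != "__config__"}
    cfg_dict["input_shape"] = tuple(cfg_dict["input_shape"])
    cfg_dict["conv_blocks"] = [tuple(b) for b in cfg_dict["conv_blocks"]]
    clf = TaskClassifier(ClassifierConfig(**cfg_dict))
    clf.load_state_dict(state)
    return clf
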