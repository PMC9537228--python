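"""Cross-validated training of the fusion network.

Protocol: stratified k-fold over the real samples; within each fold the
training split alone is balanced with mixup, the network is trained with
Adam for a fixed number of epochs, and the untouched test fold (never
containing synthetic samples) is evaluated. Per-fold metric reports are
averaged and confusion matrices summed for the final result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from gaitstream import nn
from gaitstream.augment import MixupSpec, balance_by_mixup
from gaitstream.features import build_jp, build_rjdp
from gaitstream.io import CLASSES, MotionSample
from gaitstream.metrics import MetricsReport, aggregate_reports, compute_metrics
from gaitstream.model import FusionNet, FusionNetConfig


@dataclass
class TrainConfig:
    """Optimization hyper-parameters (Adam, fixed epoch budget)."""

    epochs: int = 80
    learning_rate: float = 0.003
    batch_size: int = 57
    k_folds: int = 5
    seed: int = 0
    gate_penalty: float = 0.0   # L1 penalty on attention gate weights
    device: str = "cpu"         # informational; execution is numpy on CPU

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.k_folds < 1:
            raise ValueError("epochs, batch_size and k_folds must be positive")


def featurize_set(
    samples: list[MotionSample], classes: tuple[str, ...] = CLASSES
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack both stream tensors and one-hot labels for a list of motions."""
    if not samples:
        raise ValueError("empty sample list")
    S = np.stack([build_jp(s).S for s in samples]).astype(nn.DTYPE)
    Sp = np.stack([build_rjdp(s).S_prime for s in samples]).astype(nn.DTYPE)
    y = np.zeros((len(samples), len(classes)), dtype=np.float64)
    for n, s in enumerate(samples):
        if s.label not in classes:
            raise ValueError(f"sample {s.sample_id!r} has label {s.label!r} not in {classes}")
        y[n, classes.index(s.label)] = 1.0
    return S, Sp, y


def stratified_kfold(
    labels: list[str] | np.ndarray, k: int, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold assignment; deterministic given the seed.

    Classes with fewer than k members degrade gracefully (they are simply
    missing from some test folds); a warning is emitted in that case.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2 or k > n:
        raise ValueError(f"k must satisfy 2 <= k <= n_samples, got k={k}, n={n}")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"least populated class has {int(counts.min())} members (< k={k}); "
            "some test folds will lack that class",
            UserWarning,
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        folds = [
            (train_idx.copy(), test_idx.copy())
            for train_idx, test_idx in skf.split(np.zeros(n), labels)
        ]
    return folds


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train_fold(
    train_samples: list[MotionSample],
    cfg_model: FusionNetConfig,
    cfg_train: TrainConfig,
    test_samples: list[MotionSample] | None = None,
    classes: tuple[str, ...] = CLASSES,
) -> tuple[FusionNet, list[dict]]:
    """Train one model for the configured epoch budget.

    Returns the fitted model and a per-epoch loss log
    (``[{"epoch", "train_loss", "test_loss"}, ...]``; test loss only when a
    test set is supplied). Deterministic given the seeds in the configs.
    """
    if not train_samples:
        raise ValueError("training set is empty")
    S, Sp, y = featurize_set(train_samples, classes=classes)
    test_feats = featurize_set(test_samples, classes=classes) if test_samples else None

    model = FusionNet(cfg_model, seed=cfg_train.seed)
    optimizer = nn.Adam(model.parameters(), lr=cfg_train.learning_rate)
    rng = np.random.default_rng(cfg_train.seed)
    gates = [g for g in (model.gate_jp, model.gate_rjdp) if g is not None]

    log: list[dict] = []
    for epoch in range(cfg_train.epochs):
        losses, sizes = [], []
        for batch in _iter_batches(len(train_samples), cfg_train.batch_size, rng):
            optimizer.zero_grad()
            logits = model.forward_logits(S[batch], Sp[batch])
            loss, grad, _ = nn.softmax_cross_entropy(logits, y[batch])
            if cfg_train.gate_penalty > 0.0 and gates:
                for gate in gates:
                    w = gate.weights()
                    loss += cfg_train.gate_penalty * float(w.sum())
                    gate.graw += (cfg_train.gate_penalty * w * (1.0 - w)).astype(nn.DTYPE)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch} "
                    f"(lr={cfg_train.learning_rate})"
                )
            model.backward(grad)
            optimizer.step()
            losses.append(loss)
            sizes.append(len(batch))
        entry = {
            "epoch": epoch,
            "train_loss": float(np.average(losses, weights=sizes)),
        }
        if test_feats is not None:
            St, Spt, yt = test_feats
            test_logits = model.forward_logits(St, Spt)
            entry["test_loss"], _, _ = nn.softmax_cross_entropy(test_logits, yt)
        log.append(entry)
    return model, log


@dataclass
class CrossValResult:
    """Aggregate metrics plus per-fold artifacts from cross-validation."""

    aggregate: MetricsReport
    fold_reports: list[MetricsReport]
    fold_models: list[FusionNet]
    fold_loss_logs: list[list[dict]]
    fold_indices: list[tuple[np.ndarray, np.ndarray]]


def cross_validate(
    samples: list[MotionSample],
    cfg_model: FusionNetConfig,
    cfg_train: TrainConfig,
    mixup_spec: MixupSpec | None = None,
    classes: tuple[str, ...] = CLASSES,
    log_test_loss: bool = False,
) -> CrossValResult:
    """Stratified k-fold protocol with fold-aware mixup balancing.

    Synthetic samples are generated from training folds only; test folds
    contain exclusively real samples and every real sample is tested exactly
    once.
    """
    if any(s.synthetic for s in samples):
        raise ValueError("cross_validate expects real samples only")
    labels = [s.label for s in samples]
    folds = stratified_kfold(labels, cfg_train.k_folds, seed=cfg_train.seed)

    fold_reports, fold_models, fold_logs = [], [], []
    for fold_id, (train_idx, test_idx) in enumerate(folds):
        train = [samples[i] for i in train_idx]
        test = [samples[i] for i in test_idx]
        assert not any(s.synthetic for s in test)
        if mixup_spec is not None:
            spec = MixupSpec(
                lam=mixup_spec.lam,
                target_per_class=mixup_spec.target_per_class,
                seed=mixup_spec.seed + fold_id,
            )
            train = balance_by_mixup(train, spec, classes=classes)
        model, log = train_fold(
            train,
            cfg_model,
            cfg_train,
            test_samples=test if log_test_loss else None,
            classes=classes,
        )
        S, Sp, y = featurize_set(test, classes=classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            report = compute_metrics(y.argmax(axis=1), model.predict_proba(S, Sp), classes)
        fold_reports.append(report)
        fold_models.append(model)
        fold_logs.append(log)

    aggregate = aggregate_reports(fold_reports)
    return CrossValResult(
        aggregate=aggregate,
        fold_reports=fold_reports,
        fold_models=fold_models,
        fold_loss_logs=fold_logs,
        fold_indices=folds,
    )
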