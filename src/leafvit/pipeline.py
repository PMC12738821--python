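"""Training, evaluation and cross-validation.

The optimisation preset follows the published sweep winner: Adam at learning
rate 1e-4, 100 epochs, batch size 64, with dropout 0.5 on the head input, L2
weight decay on weight matrices, the spline curvature penalty when the head
is a KAN, and early stopping on validation loss. All randomness (shuffling,
DropPath/dropout, initialisation, splits) derives from one master seed via
named substreams, so a rerun with the same seed reproduces loss traces
bit for bit.
"""

from __future__ import annotations

import copy
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .config import ModelConfig, TrainConfig
from .core_vit import ViTClassifier, init_params, save_checkpoint
from .kan import second_derivative_gram
from .layers import softmax_cross_entropy
from .metrics import MetricsReport, compute_metrics

logger = logging.getLogger("leafvit")

__all__ = [
    "named_rng",
    "normalize_images",
    "TrainingHistory",
    "DivergenceError",
    "train_model",
    "evaluate_model",
    "crossvalidate",
]


def normalize_images(images: np.ndarray) -> np.ndarray:
    """Map [0, 1] RGB arrays to the [-1, 1] range the models are trained on."""
    return (np.asarray(images, dtype=float) - 0.5) / 0.5


def named_rng(master_seed: int, name: str) -> np.random.Generator:
    """Independent deterministic substream keyed by a stable name hash."""
    return np.random.default_rng(
        np.random.SeedSequence((int(master_seed), zlib.crc32(name.encode())))
    )


class DivergenceError(RuntimeError):
    """Raised when the loss goes non-finite; carries the last good weights."""

    def __init__(self, msg: str, last_good_params=None):
        super().__init__(msg)
        self.last_good_params = last_good_params


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    def append(self, epoch, tl, ta, vl, va):
        self.epochs.append(epoch)
        self.train_loss.append(tl)
        self.train_acc.append(ta)
        self.val_loss.append(vl)
        self.val_acc.append(va)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epochs,
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )


class _Adam:
    def __init__(self, params, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Adagrad:
    def __init__(self, params, lr, eps=1e-10):
        self.lr, self.eps = lr, eps
        self.g2 = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        for k, g in grads.items():
            self.g2[k] += g * g
            params[k] -= self.lr * g / (np.sqrt(self.g2[k]) + self.eps)


# weight decay applies to weight matrices only, not to biases, LayerNorm
# gains/shifts, or the CLS/position embeddings
_NO_DECAY_SUFFIXES = ("gamma", "beta", "b1", "b2", "/cls", "/pos")


def _decayable(name: str) -> bool:
    return not name.endswith(_NO_DECAY_SUFFIXES)


def _regularized_loss_grads(model: ViTClassifier, loss, grads, cfg: TrainConfig,
                            kan_gram: np.ndarray | None):
    wd = cfg.weight_decay
    if wd > 0:
        for k, v in model.params.items():
            if _decayable(k):
                loss += wd * float(np.sum(v * v))
                grads[k] = grads[k] + 2.0 * wd * v
    if kan_gram is not None and cfg.kan_lambda > 0:
        c = model.params["head/kan_coeffs"]
        loss += cfg.kan_lambda * float(np.einsum("ijk,kl,ijl->", c, kan_gram, c))
        grads["head/kan_coeffs"] = grads["head/kan_coeffs"] + (
            2.0 * cfg.kan_lambda * np.einsum("kl,ijl->ijk", kan_gram, c)
        )
    return loss, grads


def _dataset_loss_acc(model: ViTClassifier, X, y, batch_size=64):
    losses, correct = [], 0
    for i in range(0, len(X), batch_size):
        xb, yb = X[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward(xb)
        loss, probs, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((probs.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(X)), correct / len(X)


def train_model(
    model: ViTClassifier,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    checkpoint_path: str | None = None,
) -> TrainingHistory:
    """Optimise cross-entropy + L2 + curvature penalty with early stopping.

    The model keeps the best-validation-loss weights on return; the full
    per-epoch history (and the early-stop marker) is returned.
    """
    Xtr, ytr = train_data
    Xval, yval = val_data
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ValueError("training and validation splits must be nonempty")
    if model.config.num_classes <= int(max(ytr.max(), yval.max())):
        raise ValueError("labels exceed the configured number of classes")

    shuffle_rng = named_rng(config.seed, "shuffle")
    reg_rng = named_rng(config.seed, "regularization")
    kan_gram = (
        second_derivative_gram(model.kan_head.knots)
        if model.kan_head is not None
        else None
    )
    opt_cls = _Adam if config.optimizer == "adam" else _Adagrad
    opt = opt_cls(model.params, config.learning_rate)

    history = TrainingHistory()
    best_val = np.inf
    best_params = copy.deepcopy(model.params)
    patience_left = config.early_stopping_patience
    last_good = copy.deepcopy(model.params)

    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(len(Xtr))
        # train loss/accuracy are accumulated over the epoch's own batches
        # (pre-update), avoiding a second full pass over the training set
        run_loss, run_correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(Xtr[idx], training=True, rng=reg_rng)
            loss, probs, dlogits = softmax_cross_entropy(logits, ytr[idx])
            run_loss += loss * len(idx)
            run_correct += int((probs.argmax(axis=1) == ytr[idx]).sum())
            grads = model.backward(dlogits)
            loss, grads = _regularized_loss_grads(model, loss, grads, config, kan_gram)
            if not np.isfinite(loss):
                model.params = last_good
                raise DivergenceError(
                    f"non-finite loss at epoch {epoch}", last_good_params=last_good
                )
            opt.step(model.params, grads)
        last_good = copy.deepcopy(model.params)

        tl, ta = run_loss / len(Xtr), run_correct / len(Xtr)
        vl, va = _dataset_loss_acc(model, Xval, yval, config.batch_size)
        history.append(epoch, tl, ta, vl, va)
        logger.info(
            "epoch=%d train_loss=%.4f train_acc=%.4f val_loss=%.4f val_acc=%.4f lr=%g",
            epoch, tl, ta, vl, va, config.learning_rate,
        )
        if vl < best_val:
            best_val = vl
            history.best_epoch = epoch
            best_params = copy.deepcopy(model.params)
            patience_left = config.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                history.stopped_early = True
                logger.info("early stop at epoch %d (best %d)", epoch, history.best_epoch)
                break

    model.params = best_params
    if model.kan_head is not None:
        model.kan_head.coeffs = model.params["head/kan_coeffs"]
    if checkpoint_path is not None:
        save_checkpoint(
            checkpoint_path, model.config, model.params,
            meta={"best_epoch": history.best_epoch, "best_val_loss": best_val,
                  "train_config": config.to_dict()},
        )
    return history


def evaluate_model(
    model_or_probs: ViTClassifier | np.ndarray,
    X_or_labels: np.ndarray,
    y: np.ndarray | None = None,
    class_names=None,
) -> MetricsReport:
    """Metrics report for a model on (X, y), or directly from probabilities.

    Call as ``evaluate_model(model, X, y)`` or
    ``evaluate_model(probs, y_true)``.
    """
    if isinstance(model_or_probs, ViTClassifier):
        probs = model_or_probs.predict_proba(X_or_labels)
        y_true = np.asarray(y)
    else:
        probs = np.asarray(model_or_probs)
        y_true = np.asarray(X_or_labels)
    y_pred = probs.argmax(axis=1)
    return compute_metrics(y_true, y_pred, probs=probs, class_names=class_names)


def stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    """Per-class partition into ``folds`` validation index sets."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [val for _, val in skf.split(np.zeros(len(y)), y)]


def crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    model_factory,
    config: TrainConfig,
    folds: int = 5,
    class_names=None,
) -> dict:
    """Stratified k-fold CV; each fold once as validation/evaluation.

    ``model_factory(fold_index)`` must return a fresh ViTClassifier.
    Returns per-fold reports plus mean +/- sd aggregates.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    counts = np.bincount(y)
    if counts[counts > 0].min() < folds:
        raise ValueError("every class needs at least `folds` samples")
    reports: list[MetricsReport] = []
    for f, val_idx in enumerate(stratified_folds(y, folds, config.seed)):
        mask = np.ones(len(y), dtype=bool)
        mask[val_idx] = False
        model = model_factory(f)
        fold_cfg = TrainConfig(**{**config.to_dict(), "seed": config.seed + f})
        train_model(model, (X[mask], y[mask]), (X[val_idx], y[val_idx]), fold_cfg)
        reports.append(evaluate_model(model, X[val_idx], y[val_idx], class_names=class_names))
    accs = np.array([r.overall_accuracy for r in reports])
    return {
        "fold_reports": reports,
        "accuracy_mean": float(accs.mean()),
        "accuracy_sd": float(accs.std(ddof=1)),
        "fold_accuracies": accs.tolist(),
    }
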