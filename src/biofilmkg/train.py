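"""Training utilities: stratified splits, z-scoring, class-weighted loss,
and the full-batch training loop with patience-based early stopping.

Supervision covers microbe nodes with a disease/health label (viruses,
by default); other nodes participate only in message passing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .nn import Adam, Tensor  # noqa: F401 (Tensor re-exported for callers)

logger = logging.getLogger(__name__)


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.01
    weight_decay: float = 5e-4
    max_epochs: int = 100
    patience: int = 20
    dropout: float = 0.3
    hidden: int = 32
    seed: int = 42
    min_delta: float = 1e-5

    def __post_init__(self):
        if min(self.lr, self.max_epochs, self.patience, self.hidden) <= 0:
            raise ValueError("lr, max_epochs, patience and hidden must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclass
class SplitMasks:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __post_init__(self):
        overlap = (self.train & self.val) | (self.train & self.test) | (self.val & self.test)
        if overlap.any():
            raise ValueError("split masks overlap")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _largest_remainder(sizes: np.ndarray, frac: float, total: int) -> np.ndarray:
    quota = sizes * frac
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    elif short < 0:
        order = np.argsort(quota - base, kind="stable")
        base[order[:-short]] -= 1
    return base


def stratified_split(labels, fractions=(0.6, 0.2, 0.2), seed: int = 42) -> SplitMasks:
    """Two-stage stratified split with per-class largest-remainder rounding.

    The test share is carved out first, then the remainder is split into
    train/validation; shuffling within each class is seeded.  Classes
    with fewer than 3 members go entirely to train (with a warning).
    """
    labels = np.asarray(labels)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to stratify")
    rng = np.random.default_rng(seed)
    n = len(labels)
    train = np.zeros(n, dtype=bool)
    val = np.zeros(n, dtype=bool)
    test = np.zeros(n, dtype=bool)

    class_idx = {}
    big_classes = []
    for c in classes:
        idx = np.where(labels == c)[0]
        idx = idx[rng.permutation(len(idx))]
        if len(idx) < 3:
            logger.warning("class %r has %d members; assigning all to train",
                           c, len(idx))
            train[idx] = True
        else:
            class_idx[c] = idx
            big_classes.append(c)

    sizes = np.array([len(class_idx[c]) for c in big_classes])
    n_big = sizes.sum()
    test_frac = fractions[2]
    test_counts = _largest_remainder(sizes, test_frac,
                                     _round_half_up(test_frac * n_big))
    rem_sizes = sizes - test_counts
    val_share = fractions[1] / (fractions[0] + fractions[1])
    val_counts = _largest_remainder(rem_sizes, val_share,
                                    _round_half_up(val_share * rem_sizes.sum()))
    for c, n_test, n_val in zip(big_classes, test_counts, val_counts):
        idx = class_idx[c]
        test[idx[:n_test]] = True
        val[idx[n_test:n_test + n_val]] = True
        train[idx[n_test + n_val:]] = True
    return SplitMasks(train=train, val=val, test=test)


def zscore_features(features: np.ndarray, n_numeric: int,
                    train_mask: np.ndarray) -> np.ndarray:
    """Standardize the numeric block using training-node statistics only.

    One-hot columns (beyond ``n_numeric``) are left untouched; columns
    with zero training variance are set to 0 with a warning.
    """
    if not np.any(train_mask):
        raise ValueError("empty training mask")
    out = np.array(features, dtype=float)
    block = out[:, :n_numeric]
    mu = block[train_mask].mean(axis=0)
    sd = block[train_mask].std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d constant feature column(s) zeroed", int(degenerate.sum()))
    sd_safe = np.where(degenerate, 1.0, sd)
    z = (block - mu) / sd_safe
    z[:, degenerate] = 0.0
    out[:, :n_numeric] = z
    return out


def class_weights(counts) -> np.ndarray:
    """Inverse-frequency weights w_c = N / (K * n_c).

    Support-weighted average of the weights is exactly 1 for any counts.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError(f"every class needs a positive count, got {counts}")
    return counts.sum() / (len(counts) * counts)


def weighted_cross_entropy(probs: np.ndarray, labels: np.ndarray,
                           weights: np.ndarray, mask: np.ndarray,
                           eps: float = 1e-12) -> float:
    """Normalized weighted cross-entropy over the masked nodes."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    y = np.asarray(labels)[mask]
    p = np.clip(np.asarray(probs)[mask, y], eps, None)
    w = np.asarray(weights)[y]
    return float(-(w * np.log(p)).sum() / w.sum())


def _loss_tensor(log_probs: Tensor, labels: np.ndarray, weights: np.ndarray,
                 mask: np.ndarray) -> Tensor:
    idx = np.where(mask)[0]
    y = labels[idx]
    lp = log_probs.gather(idx)
    onehot = np.eye(log_probs.shape[1])[y]
    w = weights[y]
    total = -(lp * (onehot * w[:, None])).sum()
    return total * (1.0 / w.sum())


class EarlyStopper:
    """Stop once the epochs since the best validation loss exceed patience."""

    def __init__(self, patience: int, min_delta: float = 1e-5):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = 0
        self.epochs_since_best = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        """Record epoch's validation loss; return True when training should stop."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.best_epoch = epoch
            self.epochs_since_best = 0
            return False
        self.epochs_since_best += 1
        return self.epochs_since_best > self.patience


def train_model(model, x_raw: np.ndarray, z: np.ndarray, gt, labels: np.ndarray,
                masks: SplitMasks, config: TrainConfig):
    """Full-batch training with Adam, weighted loss and early stopping.

    Returns ``(model, history)``; the model is restored to its
    best-validation-loss state.  Deterministic given the config seed and
    a freshly constructed (seeded) model.
    """
    rng = np.random.default_rng(config.seed)  # dropout stream
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    train_y = labels[masks.train]
    counts = np.bincount(train_y, minlength=2)
    weights = class_weights(counts)

    stopper = EarlyStopper(config.patience, config.min_delta)
    history = {"train_loss": [], "val_loss": [], "train_acc": [], "val_acc": []}
    best_state = model.get_state()
    stopped_epoch = config.max_epochs

    for epoch in range(1, config.max_epochs + 1):
        out = model.forward(x_raw, z, gt, training=True, rng=rng)
        loss = _loss_tensor(out.log_probs, labels, weights, masks.train)
        if not np.isfinite(loss.data):
            raise TrainingDiverged(f"loss became non-finite at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        eval_out = model.forward(x_raw, z, gt, training=False)
        probs = eval_out.probs.data
        val_loss = weighted_cross_entropy(probs, labels, weights, masks.val)
        preds = probs.argmax(axis=1)
        history["train_loss"].append(float(loss.data))
        history["val_loss"].append(float(val_loss))
        history["train_acc"].append(float((preds[masks.train] == labels[masks.train]).mean()))
        history["val_acc"].append(float((preds[masks.val] == labels[masks.val]).mean()))

        stop = stopper.update(val_loss, epoch)
        if stopper.best_epoch == epoch:
            best_state = model.get_state()
        if stop:
            stopped_epoch = epoch
            break
    else:
        stopped_epoch = config.max_epochs

    model.set_state(best_state)
    history["best_epoch"] = stopper.best_epoch if stopper.best_epoch else 1
    history["stopped_epoch"] = stopped_epoch
    history["best_val_loss"] = float(stopper.best) if np.isfinite(stopper.best) else None
    return model, history
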