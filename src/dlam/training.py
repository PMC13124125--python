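"""Loss, optimization loop, undersampling, and threshold selection.

Training follows the protocol the architecture was designed with: Adam at
learning rate 0.009, mini-batches of 20 shuffled each epoch with a seeded
generator, and early stopping once the validation loss has gone ``patience``
consecutive epochs without improving on the running best, at which point the
best-validation weights are restored. The decision threshold for hard
classification is chosen on the validation split by maximizing F1 over a
grid, with ties broken toward 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Adam
from .model import DlamModel, softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EarlyStopping",
    "cross_entropy_loss",
    "undersample",
    "train",
    "select_threshold",
]

PROB_FLOOR = 1e-12  # documented clamp for log(0) in the loss


@dataclass
class TrainConfig:
    lr: float = 0.009
    batch_size: int = 20
    patience: int = 10
    max_epochs: int = 300
    seed: int = 0
    undersample_ratio: float | None = None  # negatives per positive
    threshold_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 101)
    )
    class_weight: tuple[float, float] | None = None

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainResult:
    model: DlamModel
    train_losses: list[float]
    val_losses: list[float]
    stopping_epoch: int
    best_epoch: int
    threshold: float
    seed: int


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without a new best loss."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record this epoch's validation loss; return True to stop."""
        if loss < self.best:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    Probabilities are clamped at ``PROB_FLOOR`` so a confident wrong
    prediction yields a large finite loss rather than infinity.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=int)
    p_true = probabilities[np.arange(len(labels)), labels]
    return float(-np.mean(np.log(np.maximum(p_true, PROB_FLOOR))))


def undersample(
    indices: np.ndarray, labels: np.ndarray, neg_per_pos: float, seed: int
) -> np.ndarray:
    """Keep all positives; subsample negatives to ``floor(n_pos * neg_per_pos)``.

    Sampling is without replacement and deterministic per seed. Raises
    ``ValueError`` if there are not enough negatives.
    """
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    pos = indices[labels[indices] == 1]
    neg = indices[labels[indices] == 0]
    n_neg = int(np.floor(len(pos) * neg_per_pos))
    if n_neg > len(neg):
        raise ValueError(f"need {n_neg} negatives, only {len(neg)} available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(neg, size=n_neg, replace=False)
    return np.sort(np.concatenate([pos, chosen]))


def _batch(blocks, flags, extra, idx):
    b = {k: v[idx] for k, v in blocks.items()}
    f = flags[idx]
    e = extra[idx] if extra is not None else None
    return b, f, e


def train(
    model: DlamModel,
    blocks: dict[str, np.ndarray],
    flags: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    cfg: TrainConfig,
    extra: np.ndarray | None = None,
) -> TrainResult:
    """Fit the model and select the decision threshold on the validation split."""
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    if np.intersect1d(train_idx, val_idx).size:
        raise ValueError("train and validation splits overlap")
    if cfg.undersample_ratio is not None:
        train_idx = undersample(train_idx, labels, cfg.undersample_ratio, cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    stopper = EarlyStopping(cfg.patience)
    best_state = model.state_dict()
    train_losses: list[float] = []
    val_losses: list[float] = []
    weight = None
    if cfg.class_weight is not None:
        weight = np.asarray(cfg.class_weight, dtype=float)
    epoch = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            b, f, e = _batch(blocks, flags, extra, idx)
            opt.zero_grad()
            logits = model.forward(b, f, extra=e, training=True, rng=rng)
            loss = softmax_cross_entropy(logits, labels[idx])
            if weight is not None:
                # reweight by replacing the mean with a class-weighted mean
                w = weight[labels[idx]]
                loss = loss * float(w.mean())
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            n_seen += len(idx)
        train_losses.append(epoch_loss / n_seen)
        vb, vf, ve = _batch(blocks, flags, extra, val_idx)
        val_probs = model.predict_proba(vb, vf, extra=ve)
        val_loss = cross_entropy_loss(val_probs, labels[val_idx])
        if not np.isfinite(val_loss):
            raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
        val_losses.append(val_loss)
        improved = val_loss < stopper.best
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.state_dict()
        if stop:
            break
    model.load_state_dict(best_state)
    vb, vf, ve = _batch(blocks, flags, extra, val_idx)
    val_probs = model.predict_proba(vb, vf, extra=ve)
    threshold = select_threshold(val_probs[:, 1], labels[val_idx], cfg.threshold_grid)
    return TrainResult(
        model=model,
        train_losses=train_losses,
        val_losses=val_losses,
        stopping_epoch=epoch,
        best_epoch=stopper.best_epoch,
        threshold=threshold,
        seed=cfg.seed,
    )


def select_threshold(
    scores: np.ndarray, labels: np.ndarray, grid: np.ndarray | None = None
) -> float:
    """Grid threshold maximizing F1 on the validation scores.

    Ties are broken toward 0.5 (then toward the lower threshold). If the
    validation labels contain a single class, F1 is uninformative and the
    fallback 0.5 is returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if len(np.unique(labels)) < 2:
        return 0.5
    best_f1 = -1.0
    best_t = 0.5
    for t in grid:
        pred = (scores >= t).astype(int)
        tp = int(np.sum((pred == 1) & (labels == 1)))
        fp = int(np.sum((pred == 1) & (labels == 0)))
        fn = int(np.sum((pred == 0) & (labels == 1)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        better = f1 > best_f1 + 1e-15
        tie = abs(f1 - best_f1) <= 1e-15 and abs(t - 0.5) < abs(best_t - 0.5) - 1e-15
        if better or tie:
            best_f1 = max(f1, best_f1)
            best_t = float(t)
    return best_t
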