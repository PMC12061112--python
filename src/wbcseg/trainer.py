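"""Training loop: Adam on summed deep-supervision binary cross-entropy.

Protocol defaults: Adam with learning rate 1e-4, 30 epochs, an 80/20
train/validation split at 256x256.  Each epoch shuffles the training set,
takes Adam steps on the sum of the BCE losses of every supervision head,
then evaluates validation loss and thresholded pixel accuracy; the returned
model carries the weights of the epoch with the best (lowest) validation
loss, ties resolved to the earliest epoch.  Everything is reproducible
under (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .io_formats import DatasetSplit
from .model import UNetPlusPlus, bce_loss, normalize_image
from .nn import Adam
from .nn import tensor as T
from .nn.tensor import Tensor

__all__ = ["TrainConfig", "TrainingHistory", "train", "epoch_accuracy"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 30
    batch_size: int = 4
    seed: int = 0
    threshold: float = 0.5  # probability cut for accuracy bookkeeping

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def to_csv(self, path) -> Path:
        import csv

        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
            for i in range(len(self.train_loss)):
                writer.writerow([i + 1, self.train_loss[i],
                                 self.train_accuracy[i], self.val_loss[i],
                                 self.val_accuracy[i]])
        return path

    def save_curves(self, path) -> Path:
        """Accuracy and loss curves per epoch, one panel each."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        epochs = np.arange(1, len(self.train_loss) + 1)
        fig, (ax_a, ax_l) = plt.subplots(1, 2, figsize=(9, 3.5))
        ax_a.plot(epochs, self.train_accuracy, label="train")
        ax_a.plot(epochs, self.val_accuracy, label="validation")
        ax_a.set_xlabel("epoch"); ax_a.set_ylabel("pixel accuracy")
        ax_a.legend()
        ax_l.plot(epochs, self.train_loss, label="train")
        ax_l.plot(epochs, self.val_loss, label="validation")
        ax_l.set_xlabel("epoch"); ax_l.set_ylabel("BCE loss")
        ax_l.legend()
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return path


def epoch_accuracy(prob_maps, masks, threshold: float = 0.5) -> float:
    """Fraction of pixels whose thresholded prediction matches the mask,
    pooled over the whole set."""
    correct = 0
    total = 0
    for p, m in zip(prob_maps, masks):
        p = np.asarray(p)
        m = np.asarray(m)
        if p.shape != m.shape:
            raise ValueError("probability map and mask shapes differ")
        correct += int(np.count_nonzero((p >= threshold) == (m > 0)))
        total += p.size
    if total == 0:
        raise ValueError("no pixels to score")
    return correct / total


_DTYPE = np.float32  # training precision: plenty for BCE + Adam, 2x faster


def _load_pairs(pairs, size: int | None):
    """Accept (path, path) or in-memory (image, mask) pairs."""
    xs, ys = [], []
    for img, msk in pairs:
        if isinstance(img, (str, Path)):
            kwargs = {} if size is None else {"size": size}
            img = io_formats.read_image(img, **kwargs).pixels
            msk = io_formats.read_mask(msk, **kwargs).pixels
        else:
            img = getattr(img, "pixels", img)
            msk = getattr(msk, "pixels", msk)
        xs.append(normalize_image(img, dtype=_DTYPE)[0])
        ys.append(np.asarray(msk, dtype=_DTYPE)[None])
    return np.stack(xs), np.stack(ys)


def train(model: UNetPlusPlus, split, config: TrainConfig | None = None,
          image_size: int | None = None):
    """Fit the model on a split; returns (best model, TrainingHistory).

    ``split`` is either a DatasetSplit of file paths or a tuple
    (train_pairs, val_pairs) of in-memory (image, mask) arrays.
    """
    config = config or TrainConfig()
    if isinstance(split, DatasetSplit):
        train_pairs, val_pairs = split.train_pairs, split.val_pairs
    else:
        train_pairs, val_pairs = split
    if not len(train_pairs) or not len(val_pairs):
        raise ValueError("train and validation sets must both be non-empty")

    x_tr, y_tr = _load_pairs(train_pairs, image_size)
    x_va, y_va = _load_pairs(val_pairs, image_size)
    model.astype(_DTYPE)

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainingHistory()
    best_val = np.inf
    best_state = model.state_dict()
    n = len(x_tr)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor(x_tr[idx])
            yb = Tensor(y_tr[idx])
            heads = model(xb)
            loss = bce_loss(heads[0], yb)
            for h in heads[1:]:
                loss = loss + bce_loss(h, yb)
            val = loss.item()
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}, step "
                    f"{start // config.batch_size + 1}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(val)
            mean_map = np.mean([h.data for h in heads], axis=0)
            correct += int(np.count_nonzero(
                (mean_map >= config.threshold) == (y_tr[idx] > 0)))
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(correct / y_tr.size)

        v_loss, v_acc = _evaluate(model, x_va, y_va, config)
        history.val_loss.append(v_loss)
        history.val_accuracy.append(v_acc)
        if v_loss < best_val:
            best_val = v_loss
            best_state = model.state_dict()
            history.best_epoch = epoch + 1

    model.load_state_dict(best_state)
    return model, history


def _evaluate(model: UNetPlusPlus, x: np.ndarray, y: np.ndarray,
              config: TrainConfig) -> tuple[float, float]:
    losses = []
    correct = 0
    with T.no_grad():
        for start in range(0, len(x), config.batch_size):
            xb = Tensor(x[start:start + config.batch_size])
            yb = y[start:start + config.batch_size]
            heads = model(xb)
            total = sum(bce_loss(h.data, yb) for h in heads)
            losses.append(total)
            mean_map = np.mean([h.data for h in heads], axis=0)
            correct += int(np.count_nonzero(
                (mean_map >= config.threshold) == (yb > 0)))
    return float(np.mean(losses)), correct / y.size
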