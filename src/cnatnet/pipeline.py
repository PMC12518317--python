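"""Training and evaluation pipeline.

Training follows the reference configuration: Adam, learning rate 0.001,
batch size 32, cross-entropy loss, 300 epochs (a desk preset of 30 epochs at
64-pixel inputs exists for CPU-scale runs). Evaluation reports accuracy from
explicit confusion counts with "premium" as the positive class, a per-level
(cluster/monomer) breakdown, and optional per-image latency.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .network import Network
from .synth import DatasetManifest, ValidationError, augment

__all__ = [
    "Hyperparams", "ConfusionCounts", "Metrics", "DataError", "Adam",
    "softmax_cross_entropy", "load_split", "train", "TrainResult",
    "evaluate", "coarse_to_fine_eval", "measure_latency",
]

LABELS = {"normal": 0, "premium": 1}  # premium is the positive class


class DataError(ValueError):
    """Raised for malformed dataset records."""


@dataclass
class Hyperparams:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 300
    seed: int = 0
    loss: str = "cross_entropy"

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValidationError(f"unsupported loss {self.loss!r}")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("learning_rate, batch_size and epochs must "
                                  "be positive")

    @classmethod
    def desk(cls, **overrides) -> "Hyperparams":
        """CPU-scale preset: 30 epochs (pair with 64-pixel inputs)."""
        kwargs = {"epochs": 30}
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def acc(self) -> float:
        if self.total == 0:
            raise ValidationError("no samples counted")
        return (self.tp + self.tn) / self.total


@dataclass
class Metrics:
    acc: float
    confusion: ConfusionCounts
    latency_ms: float | None = None
    per_level: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Optimiser and loss
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy and its gradient with respect to the logits."""
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n


# ---------------------------------------------------------------------------
# Data access
# ---------------------------------------------------------------------------

def _label_of(record) -> int:
    grade = record["grade"]
    if grade not in LABELS:
        raise DataError(f"record {record['path']!r} has grade {grade!r}; "
                        f"expected one of {sorted(LABELS)}")
    return LABELS[grade]


def load_split(manifest: DatasetManifest, split: str, size: int,
               level: str | None = None):
    """Load one split as uint8 images plus integer labels."""
    recs = manifest.records(split)
    if level is not None:
        recs = recs[recs["level"] == level]
    images, labels = [], []
    for _, r in recs.iterrows():
        labels.append(_label_of(r))
        img = Image.open(manifest.root / r["path"]).convert("RGB")
        if img.size != (size, size):
            img = img.resize((size, size), Image.BILINEAR)
        images.append(np.asarray(img))
    return images, np.array(labels, dtype=np.int64)


def _to_batch(images: list[np.ndarray]) -> np.ndarray:
    x = np.stack(images).astype(np.float32) / 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    history: dict
    best_val_acc: float
    best_epoch: int
    epochs_run: int
    best_state: dict


def train(network: Network, manifest: DatasetManifest, hp: Hyperparams,
          augment_ops: tuple = ("rotate", "hflip", "brightness", "affine"),
          stop_at_val_acc: float | None = None,
          checkpoint_path: str | Path | None = None) -> TrainResult:
    """Run the training loop; fully seeded and deterministic.

    Augmentations are applied to the training split only. The best
    checkpoint by validation accuracy is kept (and optionally saved);
    ``stop_at_val_acc`` ends training early once the validation accuracy
    reaches the given level.
    """
    size = network.cfg.input_size
    train_imgs, train_y = load_split(manifest, "train", size)
    val_imgs, val_y = load_split(manifest, "val", size)
    if len(train_imgs) == 0:
        raise ValidationError("train split is empty")
    if len(val_imgs) == 0:
        raise ValidationError("val split is empty")
    if int(train_y.max(initial=0)) >= network.num_classes:
        raise ValidationError("network num_classes does not cover label set")
    x_val = _to_batch(val_imgs)

    rng = np.random.default_rng(hp.seed)
    opt = Adam(network.parameters(), lr=hp.learning_rate)
    history = {"train_loss": [], "train_acc": [], "val_loss": [],
               "val_acc": []}
    best = (-1.0, -1, None)  # acc, epoch, state
    n = len(train_imgs)
    epochs_run = 0

    for epoch in range(hp.epochs):
        epochs_run = epoch + 1
        order = rng.permutation(n)
        network.train()
        losses, correct = [], 0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            batch = [augment(train_imgs[i], augment_ops,
                             seed=int(rng.integers(2 ** 31)))
                     for i in idx]
            x = _to_batch(batch)
            y = train_y[idx]
            logits = network(x)
            loss, dlogits = softmax_cross_entropy(logits, y)
            network.zero_grad()
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y).sum())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / n)

        network.eval()
        val_logits = network(x_val)
        val_loss, _ = softmax_cross_entropy(val_logits, val_y)
        val_acc = float((val_logits.argmax(axis=1) == val_y).mean())
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_acc > best[0]:
            best = (val_acc, epoch, copy.deepcopy(network.state_dict()))
        if stop_at_val_acc is not None and val_acc >= stop_at_val_acc:
            break

    if checkpoint_path is not None and best[2] is not None:
        from .network import save_checkpoint
        saved = copy.deepcopy(network.state_dict())
        network.load_state_dict(best[2])
        save_checkpoint(network, checkpoint_path)
        network.load_state_dict(saved)
    return TrainResult(history=history, best_val_acc=best[0],
                       best_epoch=best[1], epochs_run=epochs_run,
                       best_state=best[2])


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _confusion(pred: np.ndarray, y: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(((pred == 1) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def evaluate(network: Network, manifest: DatasetManifest, split: str = "test",
             level: str | None = None, batch_size: int = 32,
             with_latency: bool = False) -> Metrics:
    """Accuracy from confusion counts, with a per-level breakdown."""
    size = network.cfg.input_size
    images, y = load_split(manifest, split, size, level=level)
    if len(images) == 0:
        raise ValidationError(f"split {split!r}"
                              + (f" at level {level!r}" if level else "")
                              + " is empty")
    recs = manifest.records(split)
    if level is not None:
        recs = recs[recs["level"] == level]
    levels = recs["level"].to_numpy()

    network.eval()
    preds = []
    for start in range(0, len(images), batch_size):
        x = _to_batch(images[start:start + batch_size])
        preds.append(network(x).argmax(axis=1))
    pred = np.concatenate(preds)

    counts = _confusion(pred, y)
    per_level = {}
    for lv in ("cluster", "monomer"):
        m = levels == lv
        if m.any():
            c = _confusion(pred[m], y[m])
            per_level[lv] = Metrics(acc=c.acc, confusion=c)
    latency = None
    if with_latency:
        timed = images[:min(16, len(images))]
        latency = measure_latency(network, timed,
                                  warmup=min(2, len(timed) - 1))
    return Metrics(acc=counts.acc, confusion=counts, latency_ms=latency,
                   per_level=per_level)


def coarse_to_fine_eval(network_cluster: Network, network_monomer: Network,
                        manifest: DatasetManifest,
                        split: str = "test") -> tuple[Metrics, Metrics]:
    """Evaluate the cluster-level model on cluster scenes and the
    monomer-level model on monomer scenes of the same test split."""
    recs = manifest.records(split)
    for lv in ("cluster", "monomer"):
        if not (recs["level"] == lv).any():
            raise ValidationError(f"level {lv!r} absent from split {split!r}")
    m_cluster = evaluate(network_cluster, manifest, split, level="cluster")
    m_monomer = evaluate(network_monomer, manifest, split, level="monomer")
    return m_cluster, m_monomer


def measure_latency(network: Network, images: list, warmup: int = 2) -> float:
    """Mean per-image forward time in milliseconds (first ``warmup`` passes
    excluded). Informational only: hardware-dependent."""
    if len(images) == 0:
        raise ValidationError("measure_latency needs at least one image")
    if warmup < 0:
        raise ValidationError("warmup must be >= 0")
    network.eval()
    times = []
    for i, img in enumerate(images):
        x = _to_batch([img])
        t0 = time.perf_counter()
        network(x)
        t1 = time.perf_counter()
        if i >= warmup:
            times.append(t1 - t0)
    if not times:
        raise ValidationError("warmup consumed all images; nothing timed")
    return float(np.mean(times) * 1e3)
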