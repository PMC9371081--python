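"""Augmentation, stratified splitting and the seeded training loop.

The training protocol: Adam (default) or RMSprop, learning rate 3e-3, batch
size 32, 20 epochs, stratified 80/20 train/test split. Everything — weight
init, shuffling, augmentation draws, dropout — is seeded, so two runs with
the same seed produce identical loss curves. The checkpoint with the best
validation accuracy is restored into the model when training ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import rotate as _sk_rotate

from . import nn
from .canny import ImprovedCannyEdgeDetector
from .image_io import CLASSES, LabeledDataset, ValidationError, resize_to
from .model import SFNet

AUG_OPS = ("rotation", "hflip", "vflip", "scale")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 3e-3
    optimizer: str = "adam"
    split_ratio: float = 0.8
    seed: int = 0
    rotation_range: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValidationError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValidationError("batch_size and epochs must be >= 1")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValidationError(f"optimizer must be adam or rmsprop, got {self.optimizer!r}")


@dataclass
class SplitResult:
    train: LabeledDataset
    test: LabeledDataset

    @property
    def per_class_counts(self) -> dict[str, dict[str, int]]:
        return {"train": self.train.class_counts, "test": self.test.class_counts}


def _rescale_keep_shape(img: np.ndarray, factor: float) -> np.ndarray:
    """Zoom by ``factor`` about the center, then crop/pad back to the input
    shape (edge padding), so augmented images keep their size."""
    side = img.shape[0]
    new = max(3, int(round(side * factor)))
    zoomed = resize_to(img, new)
    if new == side:
        return zoomed
    if new > side:
        off = (new - side) // 2
        return zoomed[off : off + side, off : off + side]
    pad = side - new
    lo = pad // 2
    return np.pad(zoomed, ((lo, pad - lo), (lo, pad - lo)), mode="edge")


def augment(
    img: np.ndarray,
    ops: tuple[str, ...] = AUG_OPS,
    seed: int = 0,
    rotation_range: float = 15.0,
    scale_range: tuple[float, float] = (0.9, 1.1),
) -> list[np.ndarray]:
    """Return [original] + one augmented copy per requested op.

    Rotation angle and scale factor are drawn uniformly from their ranges
    with the given seed; flips are exact. All outputs keep the input shape.
    """
    unknown = set(ops) - set(AUG_OPS)
    if unknown:
        raise ValidationError(f"unknown augmentation ops {sorted(unknown)}; allowed {AUG_OPS}")
    rng = np.random.default_rng(seed)
    out = [np.array(img, dtype=np.float64)]
    for op in ops:
        if op == "rotation":
            angle = rng.uniform(-rotation_range, rotation_range)
            out.append(np.clip(_sk_rotate(out[0], angle, mode="edge"), 0.0, 1.0))
        elif op == "hflip":
            out.append(out[0][:, ::-1].copy())
        elif op == "vflip":
            out.append(out[0][::-1, :].copy())
        elif op == "scale":
            factor = rng.uniform(*scale_range)
            out.append(_rescale_keep_shape(out[0], factor))
    return out


def augment_dataset(ds: LabeledDataset, ops: tuple[str, ...] = AUG_OPS, seed: int = 0,
                    **kwargs) -> LabeledDataset:
    """Apply ``augment`` to every item of an in-memory dataset."""
    items: list[tuple[object, str]] = []
    imgs = ds.images()
    for i, ((_, label), img) in enumerate(zip(ds.items, imgs)):
        for aug in augment(img, ops=ops, seed=seed + i, **kwargs):
            items.append((aug, label))
    return LabeledDataset(items)


def split_dataset(ds: LabeledDataset, ratio: float = 0.8, seed: int = 0) -> SplitResult:
    """Stratified shuffle split: each class is shuffled and split at ``ratio``
    independently, with the test count rounded down (remainder to train)."""
    if not 0 < ratio < 1:
        raise ValidationError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    labels = np.array(ds.labels)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in CLASSES:
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValidationError(f"class {cls!r} has {idx.size} items; need >= 2 to split")
        idx = rng.permutation(idx)
        # round-before-floor so e.g. n=250, ratio=0.8 -> exactly 50 test items
        n_test = int(np.floor(round(idx.size * (1 - ratio), 6)))
        test_idx.extend(idx[:n_test].tolist())
        train_idx.extend(idx[n_test:].tolist())
    return SplitResult(train=ds.subset(sorted(train_idx)), test=ds.subset(sorted(test_idx)))


def encode_labels(labels: list[str]) -> np.ndarray:
    """fracture -> 0, healthy -> 1."""
    return np.array([CLASSES.index(l) for l in labels], dtype=np.int64)


def _loss_and_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Mean two-class cross-entropy, accuracy, and d(loss)/d(logits).

    For softmax outputs over two classes the per-class-averaged form of the
    loss equals -log P_true, whose gradient in the logits is (P - Y) / batch.
    """
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    n = len(y)
    loss = float(-logp[np.arange(n), y].mean())
    acc = float((logits.argmax(axis=1) == y).mean())
    probs = np.exp(logp)
    grad = probs.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, acc, grad / n


def evaluate_arrays(model: SFNet, grey: np.ndarray, edges: np.ndarray | None,
                    y: np.ndarray, batch_size: int = 64) -> tuple[float, float]:
    """Loss and accuracy over a dataset in inference mode."""
    losses, accs, weights = [], [], []
    for lo in range(0, len(y), batch_size):
        sl = slice(lo, lo + batch_size)
        logits = model.forward(grey[sl], None if edges is None else edges[sl], train=False)
        loss, acc, _ = _loss_and_grad(logits, y[sl])
        losses.append(loss)
        accs.append(acc)
        weights.append(len(y[sl]))
    w = np.array(weights, dtype=float)
    return float(np.average(losses, weights=w)), float(np.average(accs, weights=w))


def fit_arrays(
    model: SFNet,
    train_grey: np.ndarray,
    train_edges: np.ndarray | None,
    train_y: np.ndarray,
    cfg: TrainConfig,
    val_grey: np.ndarray | None = None,
    val_edges: np.ndarray | None = None,
    val_y: np.ndarray | None = None,
) -> dict[str, list[float]]:
    """Run the seeded training loop on materialized arrays.

    Returns a history dict with per-epoch ``train_loss``, ``train_acc`` and —
    when a validation set is given — ``val_loss``/``val_acc``; in that case
    the best-validation-accuracy weights are restored into the model before
    returning. Aborts with ``RuntimeError`` naming the epoch if the loss
    diverges to NaN.
    """
    params = model.parameters()
    if cfg.optimizer == "adam":
        opt = nn.Adam(params, lr=cfg.learning_rate)
    else:
        opt = nn.RMSprop(params, lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    has_val = val_grey is not None and val_y is not None
    history: dict[str, list[float]] = {"train_loss": [], "train_acc": []}
    if has_val:
        history["val_loss"] = []
        history["val_acc"] = []
    best_acc, best_state = -1.0, None
    n = len(train_y)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss, ep_acc, seen = 0.0, 0.0, 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            logits = model.forward(
                train_grey[idx],
                None if train_edges is None else train_edges[idx],
                train=True,
            )
            loss, acc, grad = _loss_and_grad(logits, train_y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged to non-finite loss at epoch {epoch + 1}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
            ep_acc += acc * len(idx)
            seen += len(idx)
        history["train_loss"].append(ep_loss / seen)
        history["train_acc"].append(ep_acc / seen)
        if has_val:
            vloss, vacc = evaluate_arrays(model, val_grey, val_edges, val_y)
            history["val_loss"].append(vloss)
            history["val_acc"].append(vacc)
            if vacc > best_acc:
                best_acc = vacc
                best_state = {k: v.copy() for k, v in model.state_arrays().items()}
    if best_state is not None:
        model.load_state_arrays(best_state)
    return history


def prepare_arrays(
    ds: LabeledDataset,
    side: int,
    detector: ImprovedCannyEdgeDetector | None,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Materialize a dataset as (grey stack, edge stack or None, labels)."""
    grey = np.stack([resize_to(im, side) for im in ds.images()]).astype(np.float32)
    edges = None
    if detector is not None:
        edges = detector.transform(grey).astype(np.float32)
    return grey, edges, encode_labels(ds.labels)


def train(
    model: SFNet,
    data: SplitResult,
    cfg: TrainConfig = TrainConfig(),
    detector: ImprovedCannyEdgeDetector | None = None,
) -> dict[str, list[float]]:
    """Train on a SplitResult: images are resized to the model's input side,
    edge maps precomputed with ``detector`` (defaults to the improved Canny
    detector when the model has an edge stream), then ``fit_arrays`` runs."""
    side = model.config.input_side
    if detector is None and model.use_edge_stream:
        detector = ImprovedCannyEdgeDetector()
    tg, te, ty = prepare_arrays(data.train, side, detector)
    vg, ve, vy = prepare_arrays(data.test, side, detector)
    return fit_arrays(model, tg, te, ty, cfg, val_grey=vg, val_edges=ve, val_y=vy)
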