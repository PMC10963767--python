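"""Loss, training loop, evaluation, cross-validation, experiment grid.

Training minimizes mean cross-entropy with Adam (lr 1e-4 decaying on
validation plateau to a floor of 1e-5, batch size 32, 100 epochs in the
reference configuration; desk-scale runs shrink the batch/epoch budget,
not the procedure). Augmentation is applied on the fly to training
batches only; the checkpoint with the best validation accuracy is the
one evaluated. All randomness derives from ``TrainConfig.seed``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .augment import AugmentConfig, Transform, build_transform
from .autodiff import Tensor, log_softmax, softmax
from .bodymap import BodyMap, canonical_bodymap, encode_location
from .manifest import DatasetSplit, Manifest, SplitSpec, make_cv_folds, select_classes, split_dataset
from .metrics import MetricsReport, compute_metrics
from .network import FusionNetwork, NetworkConfig, build_network
from .nn import Adam, ReduceLROnPlateau
from .synthetic import load_image

__all__ = [
    "TrainConfig",
    "cross_entropy",
    "train",
    "evaluate",
    "run_crossval",
    "aggregate_fold_accuracies",
    "run_experiment_grid",
]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    lr_min: float = 1e-5
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    grad_clip: float = 5.0  # global-norm clip; 0 disables
    warmup_epochs: int = 0  # linear lr ramp from lr/10; stabilizes attention nets

    def __post_init__(self):
        if not self.lr >= self.lr_min > 0:
            raise ValueError("need lr >= lr_min > 0")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


# ---------------------------------------------------------------------------
# Loss

_EPS = 1e-12


def cross_entropy(p, y) -> float:
    """Cross-entropy of a predicted probability vector against a label.

    Multi-class: ``p`` is a probability vector, ``y`` a class index (or a
    one-hot vector); L = -sum_i y_i log p_i = -log p_y. Binary: ``p`` is
    the scalar predicted probability of the positive class and ``y`` in
    {0, 1}; L = -[y log p + (1-y) log(1-p)]. Probabilities are clamped at
    1e-12 for numerical safety.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim == 0:
        yv = float(y)
        if not 0.0 <= p <= 1.0 or yv not in (0.0, 1.0):
            raise ValueError("binary cross-entropy needs p in [0,1] and y in {0,1}")
        pc = np.clip(p, _EPS, 1 - _EPS)
        return float(-(yv * np.log(pc) + (1 - yv) * np.log(1 - pc)))
    if p.ndim != 1:
        raise ValueError("p must be a probability vector or a scalar probability")
    if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"invalid probability vector (sum={p.sum()!r})")
    y_arr = np.asarray(y)
    if y_arr.ndim == 0:
        yi = int(y_arr)
        if not 0 <= yi < p.size:
            raise ValueError(f"label {yi} out of range for {p.size} classes")
        return float(-np.log(max(p[yi], _EPS)))
    if y_arr.shape != p.shape:
        raise ValueError("one-hot label must match p in shape")
    return float(-(y_arr * np.log(np.clip(p, _EPS, None))).sum())


def _clip_grad_norm(net, max_norm: float) -> None:
    params = [p for p in net.parameters() if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad**2).sum()) for p in params)))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.grad *= scale


def _batch_ce(logits: Tensor, y_idx: np.ndarray) -> Tensor:
    """Mean cross-entropy from logits (stable log-softmax path)."""
    logp = log_softmax(logits, axis=1)
    picked = logp[np.arange(len(y_idx)), y_idx]
    return -picked.mean()


# ---------------------------------------------------------------------------
# Data assembly

class _Loaded:
    """Raw images + labels + one-hot locations for one manifest."""

    def __init__(self, manifest: Manifest, bmap: BodyMap, use_location: bool):
        self.images = [load_image(r.image_ref) for r in manifest.records]
        self.y = manifest.label_indices()
        self.classes = manifest.classes
        if use_location:
            rows = []
            for r in manifest.records:
                if r.location_id is None:
                    rows.append(np.zeros(bmap.size))  # BG/N: no anatomical location
                else:
                    rows.append(encode_location(bmap, r.location_id))
            self.loc = np.stack(rows)
        else:
            self.loc = None

    def transformed(self, tf: Transform, rng=None) -> np.ndarray:
        return np.stack([tf.apply(img, rng) for img in self.images])


def _forward_batches(net: FusionNetwork, X: np.ndarray, loc: np.ndarray | None,
                     batch_size: int = 64) -> np.ndarray:
    outs = []
    for i in range(0, len(X), batch_size):
        l = None if loc is None else Tensor(loc[i : i + batch_size])
        logits = net(Tensor(X[i : i + batch_size]), l)
        outs.append(softmax(logits, axis=1).data)
    return np.concatenate(outs)


# ---------------------------------------------------------------------------
# Training

def train(
    net: FusionNetwork,
    split: DatasetSplit,
    tc: TrainConfig,
    augment: AugmentConfig | None = None,
    bmap: BodyMap | None = None,
) -> tuple[FusionNetwork, list[dict]]:
    """Fit ``net`` on ``split.train``, model-selecting on ``split.val``.

    Returns the network (restored to its best-validation-accuracy
    weights) and the per-epoch history (train loss, validation loss and
    accuracy, learning rate).
    """
    if len(split.train) == 0:
        raise ValueError("training set is empty")
    cfg = net.config
    bmap = bmap or canonical_bodymap()
    augment = augment or AugmentConfig(target_size=(cfg.image_size, cfg.image_size))
    if augment.target_size != (cfg.image_size, cfg.image_size):
        raise ValueError("augment target_size must match the network's image_size")

    rng = np.random.default_rng(tc.seed)
    train_tf = build_transform(augment, seed=int(rng.integers(2**31)), training=True)
    eval_tf = build_transform(augment, seed=0, training=False)

    tr = _Loaded(split.train, bmap, cfg.use_location)
    va = _Loaded(split.val, bmap, cfg.use_location) if len(split.val) else None
    X_val = va.transformed(eval_tf) if va else None

    opt = Adam(net.parameters(), lr=tc.lr)
    sched = ReduceLROnPlateau(opt, factor=tc.plateau_factor,
                              patience=tc.plateau_patience, min_lr=tc.lr_min)
    history: list[dict] = []
    best_acc, best_state = -1.0, copy.deepcopy(net.state_dict())

    n = len(tr.images)
    for epoch in range(tc.epochs):
        net.train()
        if tc.warmup_epochs and epoch < tc.warmup_epochs:
            opt.lr = tc.lr * (0.1 + 0.9 * (epoch + 1) / tc.warmup_epochs)
        elif tc.warmup_epochs and epoch == tc.warmup_epochs:
            opt.lr = tc.lr
        epoch_rng = np.random.default_rng(tc.seed * 100003 + epoch)
        X = tr.transformed(train_tf, epoch_rng)
        order = epoch_rng.permutation(n)
        losses = []
        for i in range(0, n, tc.batch_size):
            idx = order[i : i + tc.batch_size]
            loc = None if tr.loc is None else Tensor(tr.loc[idx])
            logits = net(Tensor(X[idx]), loc)
            loss = _batch_ce(logits, tr.y[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // tc.batch_size}: {loss.item()}"
                )
            opt.zero_grad()
            loss.backward()
            if tc.grad_clip > 0:
                _clip_grad_norm(net, tc.grad_clip)
            opt.step()
            losses.append(loss.item())

        entry = {"epoch": epoch, "train_loss": float(np.mean(losses)), "lr": opt.lr}
        if va:
            net.eval()
            probs = _forward_batches(net, X_val, va.loc)
            val_loss = float(np.mean([cross_entropy(probs[j], va.y[j]) for j in range(len(va.y))]))
            val_acc = float(np.mean(probs.argmax(axis=1) == va.y)) * 100.0
            entry.update(val_loss=val_loss, val_acc=val_acc)
            sched.step(val_loss)
            if val_acc > best_acc:
                best_acc = val_acc
                best_state = copy.deepcopy(net.state_dict())
        history.append(entry)

    if va:
        net.load_state_dict(best_state)
    net.eval()
    return net, history


def evaluate(
    net: FusionNetwork,
    manifest: Manifest,
    augment: AugmentConfig | None = None,
    bmap: BodyMap | None = None,
) -> MetricsReport:
    """Metrics of ``net`` on a manifest (resize+normalize only, no augmentation)."""
    if len(manifest) == 0:
        raise ValueError("cannot evaluate on an empty manifest")
    cfg = net.config
    bmap = bmap or canonical_bodymap()
    augment = augment or AugmentConfig(target_size=(cfg.image_size, cfg.image_size))
    eval_tf = build_transform(augment, seed=0, training=False)
    data = _Loaded(manifest, bmap, cfg.use_location)
    net.eval()
    probs = _forward_batches(net, data.transformed(eval_tf), data.loc)
    return compute_metrics(data.y, probs.argmax(axis=1), probs, classes=manifest.classes)


# ---------------------------------------------------------------------------
# Cross-validation

def aggregate_fold_accuracies(fold_accuracies: list[float]) -> float:
    """The AVG column: arithmetic mean of fold accuracies, 2 decimals."""
    return round(float(np.mean(fold_accuracies)), 2)


def run_crossval(
    manifest: Manifest,
    net_config: NetworkConfig,
    tc: TrainConfig,
    k: int = 5,
    augment: AugmentConfig | None = None,
    val_fraction: float = 0.15,
) -> dict:
    """k-fold cross-validation: k independent models, fold accuracies + mean.

    Each fold's training portion donates ``val_fraction`` for the plateau
    schedule and checkpoint selection; the held-out fold is test-only.
    """
    folds = make_cv_folds(manifest, k, seed=tc.seed)
    accs: list[float] = []
    for fi, (fold_train, fold_test) in enumerate(folds):
        try:
            inner = split_dataset(
                fold_train, SplitSpec((1.0 - val_fraction, val_fraction, 0.0), seed=tc.seed)
            )
            net = build_network(net_config, seed=tc.seed + fi)
            net, _ = train(net, DatasetSplit(inner.train, inner.val, fold_test), tc, augment)
            report = evaluate(net, fold_test, augment)
        except Exception as err:
            raise RuntimeError(f"cross-validation fold {fi} failed: {err}") from err
        accs.append(round(report.accuracy, 2))
    return {"fold_accuracies": accs, "avg": aggregate_fold_accuracies(accs), "k": k}


# ---------------------------------------------------------------------------
# Experiment grid

def run_experiment_grid(
    manifest: Manifest,
    subsets: list[tuple[str, ...]],
    splits: list[SplitSpec],
    net_config: NetworkConfig,
    tc: TrainConfig,
    augment: AugmentConfig | None = None,
) -> list[dict]:
    """Class-combination x split-spec grid: select, split, train, evaluate.

    One result row per cell with accuracy/precision/recall/F1 (percent,
    2 decimals); a failing cell records its error and the grid continues.
    """
    rows: list[dict] = []
    for subset in subsets:
        for spec in splits:
            row: dict = {
                "classes": ",".join(subset),
                "split": "/".join(f"{f:g}" for f in spec.fractions),
            }
            try:
                sub = select_classes(manifest, subset)
                split = split_dataset(sub, spec)
                from dataclasses import replace

                cfg = replace(net_config, num_classes=len(subset))
                net = build_network(cfg, seed=tc.seed)
                net, _ = train(net, split, tc, augment)
                rep = evaluate(net, split.test, augment)
                row.update(
                    A=round(rep.accuracy, 2),
                    P=round(rep.precision, 2),
                    R=round(rep.recall, 2),
                    F=round(rep.f1, 2),
                )
            except Exception as err:  # grid must survive cell failures
                row["error"] = str(err)
            rows.append(row)
    return rows
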