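"""Training loop for the segmentation network.

Adam with the pipeline's stock hyperparameters (lr 0.003, decay factor 0.5,
batch size 4); the learning rate is step-decayed by the decay factor every
``decay_every`` epochs.  Gradients are accumulated per cloud over a batch
and averaged.  The best checkpoint is selected by validation mIoU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io import LabeledPointCloud
from .autodiff import Tensor, softmax
from .metrics import miou
from .network import NetworkConfig, RelationAttentionSegNet

__all__ = ["TrainingParams", "TrainResult", "Adam", "train_segmentation"]


@dataclass
class TrainingParams:
    lr: float = 0.003
    decay: float = 0.5
    decay_every: int = 20
    batch_size: int = 4
    epochs: int = 200
    val_fraction: float = 0.2
    seed: int = 0


@dataclass
class TrainResult:
    model: RelationAttentionSegNet
    history: list = field(default_factory=list)  # per-epoch dicts
    best_epoch: int = -1
    best_val_miou: float = float("nan")


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else 0.0
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _tensor_cross_entropy(scores: Tensor, labels: np.ndarray) -> Tensor:
    probs = softmax(scores, axis=-1)
    onehot = np.zeros(scores.shape)
    onehot[np.arange(len(labels)), labels] = 1.0
    true_p = (probs * Tensor(onehot)).sum(axis=-1)
    return -(true_p + 1e-12).log().mean()


def _snapshot(model: RelationAttentionSegNet) -> dict:
    return {k: v.copy() for k, v in model._named_state().items()}


def _restore(model: RelationAttentionSegNet, snap: dict) -> None:
    for k, v in model._named_state().items():
        v[...] = snap[k]


def train_segmentation(
    dataset: list[LabeledPointCloud],
    config: NetworkConfig,
    params: TrainingParams | None = None,
    val: list[LabeledPointCloud] | None = None,
) -> TrainResult:
    """Train on labelled clouds of a common size; returns the checkpoint
    with the best validation mIoU plus the per-epoch metric log.

    If no explicit validation set is given, ``val_fraction`` of the dataset
    (at least one cloud) is deterministically held out.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    sizes = {len(lc) for lc in dataset} | ({len(lc) for lc in val} if val else set())
    if len(sizes) != 1:
        raise ValueError(f"all clouds must share one size, got sizes {sorted(sizes)}")
    hp = params if params is not None else TrainingParams()
    rng = np.random.default_rng(hp.seed)
    if val is None:
        n_val = max(1, int(round(hp.val_fraction * len(dataset))))
        if n_val >= len(dataset):
            raise ValueError("dataset too small to split a validation set")
        order = rng.permutation(len(dataset))
        val = [dataset[i] for i in order[:n_val]]
        dataset = [dataset[i] for i in order[n_val:]]

    model = RelationAttentionSegNet(config)
    # pre-build the geometry pyramids once; they never change
    train_pyrs = [model.pyramid_for(lc.cloud.points, cache_key=("tr", i)) for i, lc in enumerate(dataset)]
    val_pyrs = [model.pyramid_for(lc.cloud.points, cache_key=("va", i)) for i, lc in enumerate(val)]

    opt = Adam(model.parameters(), lr=hp.lr)
    result = TrainResult(model=model)
    best = -np.inf
    best_state = _snapshot(model)
    for epoch in range(hp.epochs):
        opt.lr = hp.lr * hp.decay ** (epoch // hp.decay_every)
        order = rng.permutation(len(dataset))
        losses = []
        for b0 in range(0, len(order), hp.batch_size):
            batch = order[b0 : b0 + hp.batch_size]
            opt.zero_grad()
            batch_losses = []
            for i in batch:
                scores = model.forward(train_pyrs[i], training=True)
                loss = _tensor_cross_entropy(scores, dataset[i].labels)
                loss.backward(np.asarray(1.0 / len(batch)))
                batch_losses.append(float(loss.data))
            opt.step()
            losses.extend(batch_losses)
        val_mious = [
            miou(np.argmax(model.forward(p).data, axis=1), lc.labels, config.num_classes)
            for p, lc in zip(val_pyrs, val)
        ]
        entry = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "val_miou": float(np.mean(val_mious)),
        }
        result.history.append(entry)
        if entry["val_miou"] > best:
            best = entry["val_miou"]
            best_state = _snapshot(model)
            result.best_epoch = epoch
    _restore(model, best_state)
    result.best_val_miou = best
    return result
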