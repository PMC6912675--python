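"""Training protocol and cross-validation harness.

The training contract mirrors the original training protocol: mean-squared-error
loss on the target heatmaps, SGD with Nesterov momentum 0.9, L2 penalty
1e-5 on convolution weights only (group-norm affines and biases exempt), an
initial learning rate of 0.01 halved on epoch 100, 120 epochs, an effective
total batch of 4 realized as 2 per replica x 2 replicas (a single-device
run uses gradient accumulation of 2 x 2, which is contractually
equivalent), and model selection from the validation-best checkpoint after
epoch 80.  Epochs are 1-based, and "on epoch 100" means the halved rate
applies during epoch 100.

The 10-fold cross-validation plan is a seeded uniform random partition into
folds whose sizes differ by at most one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .engine import SGDNesterov
from .heatmaps import HeatmapSpec, build_targets
from .model import ModelConfig, ResUNet, UNet12, build_model
from .preprocess import AugmentParams, ImageRecord, PreprocessSpec, augment, resize_pad
from .synthetic import SyntheticAnnotatedImage

__all__ = [
    "FoldPlan",
    "History",
    "TrainConfig",
    "HeatmapDataset",
    "hyperparameter_grid",
    "learning_rate",
    "make_folds",
    "mse_heatmap_loss",
    "select_checkpoint",
    "train_model",
]


@dataclass(frozen=True)
class TrainConfig:
    per_replica_batch: int = 2
    replicas: int = 2
    epochs: int = 120
    lr_initial: float = 0.01
    lr_halve_epoch: int = 100
    momentum: float = 0.9
    l2_strength: float = 1e-5
    checkpoint_min_epoch: int = 80
    seed: int = 0
    augment_params: AugmentParams | None = None

    def __post_init__(self) -> None:
        if min(self.per_replica_batch, self.replicas, self.epochs) < 1:
            raise ValueError("batch, replicas and epochs must be positive")
        if self.lr_initial < 0 or self.lr_halve_epoch < 1:
            raise ValueError("learning rate must be non-negative and halve epoch >= 1")
        if not 0 <= self.checkpoint_min_epoch < self.epochs:
            raise ValueError("checkpoint_min_epoch must lie in [0, epochs)")

    @property
    def total_batch(self) -> int:
        return self.per_replica_batch * self.replicas


@dataclass(frozen=True)
class FoldPlan:
    assignments: tuple[int, ...]  # image index -> fold id in 1..k
    k: int

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignments) == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignments) != fold)


@dataclass
class History:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def learning_rate(epoch: int, config: TrainConfig) -> float:
    """Step schedule: initial rate, halved from ``lr_halve_epoch`` onward."""
    if not 1 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside 1..{config.epochs}")
    return config.lr_initial if epoch < config.lr_halve_epoch else config.lr_initial / 2.0


def mse_heatmap_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over all pixels and channels of the squared difference.

    The optimizer adds the L2 weight penalty separately; it is not part of
    this function.
    """
    p = np.asarray(pred, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean((p - t) ** 2))


def make_folds(n: int, k: int, seed: int) -> FoldPlan:
    """Seeded uniform random partition into ``k`` folds of size floor/ceil(n/k)."""
    if k < 2:
        raise ValueError("need at least 2 folds")
    if n < k:
        raise ValueError(f"cannot split {n} images into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    # Fold sizes differ by at most one: the first n % k folds get the extra image.
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    start = 0
    for fold_id, size in enumerate(sizes, start=1):
        assignments[order[start : start + size]] = fold_id
        start += size
    return FoldPlan(assignments=tuple(int(a) for a in assignments), k=k)


def select_checkpoint(history: History, config: TrainConfig) -> int:
    """1-based epoch of the best validation loss among epochs > checkpoint_min_epoch.

    Ties resolve to the earliest qualifying epoch.
    """
    n = len(history.val_loss)
    if n <= config.checkpoint_min_epoch:
        raise ValueError(
            f"history covers {n} epochs; need more than {config.checkpoint_min_epoch}"
        )
    window = history.val_loss[config.checkpoint_min_epoch :]
    best = int(np.argmin(window))  # argmin returns the first minimum
    return config.checkpoint_min_epoch + best + 1


class HeatmapDataset:
    """Pairs each annotated record with its target heatmap stack on the network canvas.

    Records pass through resize/pad once; targets are rendered from the
    canvas-frame landmarks.  With augmentation enabled, each access applies
    a seeded draw to the canvas image and re-renders the targets at the
    transformed landmarks.
    """

    def __init__(
        self,
        images: Sequence[SyntheticAnnotatedImage | ImageRecord],
        heatmap_spec: HeatmapSpec,
        preprocess_spec: PreprocessSpec,
        augment_params: AugmentParams | None = None,
    ):
        if len(images) == 0:
            raise ValueError("empty dataset")
        self.heatmap_spec = heatmap_spec
        self.preprocess_spec = preprocess_spec
        self.augment_params = augment_params
        self._canvases: list[np.ndarray] = []
        self._points: list[list] = []
        for im in images:
            record = im.record if isinstance(im, SyntheticAnnotatedImage) else im
            canvas, points, _ = resize_pad(record, preprocess_spec)
            if points is None:
                raise ValueError("training records must carry landmarks")
            self._canvases.append(canvas)
            self._points.append(points)

    def __len__(self) -> int:
        return len(self._canvases)

    def sample(self, i: int, seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(H x W x 1 input, H x W x K target); ``seed`` enables augmentation."""
        canvas, points = self._canvases[i], self._points[i]
        if self.augment_params is not None and seed is not None:
            canvas, points = augment(canvas, points, self.augment_params, seed=seed)
        h, w = canvas.shape
        targets = build_targets(points, self.heatmap_spec, h, w)
        return canvas[..., None].astype(np.float32), targets.values.astype(np.float32)


def _epoch_loss(model, dataset: HeatmapDataset, batch: int) -> float:
    """Mean per-sample MSE over the dataset, without augmentation."""
    losses = []
    for start in range(0, len(dataset), batch):
        xs, ts = zip(*(dataset.sample(i) for i in range(start, min(start + batch, len(dataset)))))
        pred = model.forward(np.stack(xs))
        losses.append(mse_heatmap_loss(pred, np.stack(ts)))
    return float(np.mean(losses))


def train_model(
    dataset: HeatmapDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    val_dataset: HeatmapDataset | None = None,
) -> tuple[ResUNet | UNet12, History]:
    """Train with SGD/Nesterov and return the selected-checkpoint model.

    Gradient accumulation over ``replicas`` micro-batches of
    ``per_replica_batch`` reproduces the total batch of 4 on one device.
    Checkpoint selection uses validation MSE when a validation set is given;
    otherwise the final weights are returned.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    model = build_model(model_config, seed=train_config.seed)
    params = model.params()
    opt = SGDNesterov(
        params,
        lr=train_config.lr_initial,
        momentum=train_config.momentum,
        weight_decay=train_config.l2_strength,
    )
    rng = np.random.default_rng(train_config.seed)
    history = History()
    n = len(dataset)
    total_batch = train_config.total_batch
    best_val = np.inf
    best_weights: list[np.ndarray] | None = None
    best_epoch = -1

    for epoch in range(1, train_config.epochs + 1):
        opt.lr = learning_rate(epoch, train_config)
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, total_batch):
            idx = order[start : start + total_batch]
            if len(idx) == 0:
                continue
            opt.zero_grad()
            n_micro = 0
            for mstart in range(0, len(idx), train_config.per_replica_batch):
                midx = idx[mstart : mstart + train_config.per_replica_batch]
                xs, ts = [], []
                for i in midx:
                    aug_seed = None
                    if train_config.augment_params is not None:
                        aug_seed = int(rng.integers(0, 2**31 - 1))
                    x, t = dataset.sample(int(i), seed=aug_seed)
                    xs.append(x)
                    ts.append(t)
                x = np.stack(xs)
                t = np.stack(ts)
                pred = model.forward(x)
                epoch_losses.append(mse_heatmap_loss(pred, t))
                dpred = ((2.0 / pred.size) * (pred - t)).astype(pred.dtype)
                model.backward(dpred)
                n_micro += 1
            if n_micro > 1:
                for p in params:
                    p.grad /= n_micro
            opt.step()
        history.train_loss.append(float(np.mean(epoch_losses)))
        if val_dataset is not None:
            vloss = _epoch_loss(model, val_dataset, total_batch)
            history.val_loss.append(vloss)
            if epoch > train_config.checkpoint_min_epoch and vloss < best_val:
                best_val = vloss
                best_epoch = epoch
                best_weights = [p.value.copy() for p in params]

    if best_weights is not None:
        for p, w in zip(params, best_weights):
            p.value = w
    return model, history


def hyperparameter_grid(
    sigmas: Sequence[float] = (6.28, 3.14, 1.57, 0.79),
    families: Sequence[str] = ("exponential", "gaussian"),
    amplitude: float = 1000.0,
) -> list[HeatmapSpec]:
    """The model-selection sweep: both target families at each heatmap width."""
    return [
        HeatmapSpec(family=f, sigma=s, amplitude=amplitude)
        for f in families
        for s in sigmas
    ]
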