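"""Single-task and unified multi-task optimization.

Unified training draws single-task batches from all task datasets in a
balanced round-robin, so every degradation kind receives the same number of
gradient steps per epoch regardless of dataset size — unbalanced sampling
would confound any comparison of task interference.  Single-task training is
the same loop run with one dataset.

The whole network — backbone, ARC encoder, instruction dictionary and the
per-block modulation MLPs — is optimized jointly from the restoration loss;
no degradation labels reach the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .degradations import PairedSample
from .image import ImageSlice, ValidationError
from .metrics import psnr
from .model import MiraNet


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 3
    batch_size: int = 4
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "l1"
    sampling: str = "balanced_round_robin"
    schedule: str = "cosine"
    seed: int = 0
    deterministic_mode: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValidationError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.loss not in _LOSS_FNS:
            raise ValidationError(f"unknown loss {self.loss!r}")
        if self.sampling not in ("balanced_round_robin", "proportional"):
            raise ValidationError(f"unknown sampling strategy {self.sampling!r}")
        if self.schedule not in ("cosine", "none"):
            raise ValidationError(f"unknown schedule {self.schedule!r}")


@dataclass
class TaskDataset:
    """Partitioned paired samples for one degradation task."""

    task: str
    train: list[PairedSample]
    val: list[PairedSample] = field(default_factory=list)
    test: list[PairedSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        for part in (self.train, self.val, self.test):
            for s in part:
                if s.degradation_label != self.task:
                    raise ValidationError(
                        f"sample labelled {s.degradation_label!r} in dataset {self.task!r}")


@dataclass
class TrainingHistory:
    """Per-epoch mean training loss and per-task validation PSNR."""

    train_loss: list[float] = field(default_factory=list)
    val_psnr: dict[str, list[float]] = field(default_factory=dict)


_LOSS_FNS = {"l1": nn.l1_loss, "l2": nn.l2_loss, "charbonnier": nn.charbonnier_loss}


def loss(restored: ImageSlice, reference: ImageSlice, kind: str = "l1") -> float:
    """Restoration objective between two slices (scalar, nonnegative)."""
    if restored.shape != reference.shape:
        raise ValidationError("images must share shape")
    a, b = restored.pixels, reference.pixels
    if kind == "l1":
        return float(np.abs(a - b).mean())
    if kind == "l2":
        return float(((a - b) ** 2).mean())
    if kind == "charbonnier":
        return float(np.sqrt((a - b) ** 2 + 1e-6).mean())
    raise ValidationError(f"unknown loss {kind!r}")


def make_batches(datasets: list[TaskDataset], config: TrainingConfig,
                 epoch: int = 0) -> list[tuple[str, list[PairedSample]]]:
    """Deterministic single-task batch schedule for one epoch.

    ``balanced_round_robin`` cycles tasks; every task contributes the same
    number of batches per epoch (that of the largest dataset), smaller tasks
    wrapping around their reshuffled sample stream.  ``proportional``
    concatenates each task's batches and shuffles the order.
    """
    if not datasets or any(len(d.train) == 0 for d in datasets):
        raise ValidationError("every dataset needs a non-empty train partition")
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(epoch,)))
    bs = config.batch_size

    per_task: dict[str, list[list[PairedSample]]] = {}
    if config.sampling == "balanced_round_robin":
        n_batches = max(math.ceil(len(d.train) / bs) for d in datasets)
        for d in datasets:
            order = list(rng.permutation(len(d.train)))
            while len(order) < n_batches * bs:
                order.extend(rng.permutation(len(d.train)))
            per_task[d.task] = [[d.train[j] for j in order[i * bs:(i + 1) * bs]]
                                for i in range(n_batches)]
        schedule = []
        for i in range(n_batches):
            for d in datasets:
                schedule.append((d.task, per_task[d.task][i]))
        return schedule

    schedule = []
    for d in datasets:
        order = list(rng.permutation(len(d.train)))
        for i in range(math.ceil(len(order) / bs)):
            chunk = [d.train[j] for j in order[i * bs:(i + 1) * bs]]
            schedule.append((d.task, chunk))
    rng.shuffle(schedule)
    return schedule


def _stack(samples: list[PairedSample]) -> tuple[np.ndarray, np.ndarray]:
    """Channels-last (N, H, W, 1) batches for the network."""
    x = np.stack([s.low_quality.pixels for s in samples])[..., None].astype(np.float32)
    y = np.stack([s.high_quality.pixels for s in samples])[..., None].astype(np.float32)
    return x, y


def _validation_psnr(model: MiraNet, dataset: TaskDataset,
                     use_modulation: bool, chunk: int = 25) -> float:
    """Mean validation PSNR, evaluated in batched forward passes."""
    lo, hi = dataset.val[0].low_quality.intensity_range
    h, w = dataset.val[0].low_quality.shape
    m = 2 ** (model.config.depth - 1)
    if h % m or w % m:  # awkward sizes go through the padded per-slice path
        vals = [psnr(model.restore(s.low_quality, use_modulation=use_modulation),
                     s.high_quality) for s in dataset.val]
        finite = [v for v in vals if np.isfinite(v)]
        return float(np.mean(finite)) if finite else float("inf")
    vals = []
    for i in range(0, len(dataset.val), chunk):
        part = dataset.val[i:i + chunk]
        x, y = _stack(part)
        out, _, _ = model.forward(nn.Tensor(x), use_modulation=use_modulation)
        rec = np.clip(out.numpy().astype(np.float64), lo, hi)
        for k, s in enumerate(part):
            vals.append(psnr(s.high_quality.with_pixels(rec[k, :, :, 0]), s.high_quality))
    finite = [v for v in vals if np.isfinite(v)]
    return float(np.mean(finite)) if finite else float("inf")


def train(model: MiraNet, datasets: list[TaskDataset], config: TrainingConfig,
          use_modulation: bool = True) -> tuple[MiraNet, TrainingHistory]:
    """Optimize the model end-to-end; returns it with its history.

    ``use_modulation=False`` trains the ablated variant: the backbone runs
    with modulation skipped entirely (gamma = 1, beta = 0 frozen), so the ARC
    receives no gradient and the network degenerates to a plain shared U-Net.
    """
    if config.optimizer != "adam":
        raise ValidationError(f"unknown optimizer {config.optimizer!r}")
    loss_fn = _LOSS_FNS[config.loss]
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    history = TrainingHistory(val_psnr={d.task: [] for d in datasets})
    total_steps = config.epochs * len(make_batches(datasets, config, 0))
    step = 0

    for epoch in range(config.epochs):
        batch_losses = []
        for _task, samples in make_batches(datasets, config, epoch):
            if config.schedule == "cosine":
                # decay to 5% of the base rate over the full run
                frac = 0.05 + 0.95 * 0.5 * (1 + math.cos(math.pi * step / total_steps))
                opt.lr = config.learning_rate * frac
            step += 1
            x, y = _stack(samples)
            out, _, _ = model.forward(nn.Tensor(x), use_modulation=use_modulation)
            l = loss_fn(out, y)
            if not np.isfinite(l.item()):
                raise TrainingDivergedError(epoch)
            opt.zero_grad()
            l.backward()
            opt.step()
            batch_losses.append(l.item())
        history.train_loss.append(float(np.mean(batch_losses)))
        for d in datasets:
            if d.val:
                history.val_psnr[d.task].append(
                    _validation_psnr(model, d, use_modulation))
    return model, history
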