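"""Training and evaluation protocol.

AdamW at an initial learning rate of 1e-3 with a reduce-on-plateau schedule
(monitoring validation mIoU, factor 0.5, patience 5 validations), focal loss,
validation every two epochs, retention of the five best checkpoints by
validation mIoU, and test metrics computed per checkpoint and then averaged
arithmetically across the retained checkpoints.
"""

from __future__ import annotations

import csv
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .config import ModelConfig, TrainConfig
from .decoder import LDCNetSegmenter, build_model
from .losses import FocalLossConfig, focal_loss
from .metrics import MetricsReport, confusion_matrix, mean_iou
from .synthetic import DatasetManifest, SplitSpec, load_pair


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

@dataclass(order=True)
class CheckpointEntry:
    val_miou: float
    epoch: int = field(compare=False)
    path: str = field(compare=False)


@dataclass
class CheckpointSet:
    """Up to ``top_k`` parameter snapshots, best validation mIoU first."""

    top_k: int = 5
    entries: list = field(default_factory=list)

    def offer(self, val_miou, epoch, state, directory):
        """Keep the snapshot iff it ranks in the current top-k."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if len(self.entries) == self.top_k and val_miou <= self.entries[-1].val_miou:
            return False
        path = directory / f"epoch_{epoch:04d}.npz"
        nn.save_state(path, state)
        self.entries.append(CheckpointEntry(float(val_miou), epoch, str(path)))
        self.entries.sort(key=lambda e: e.val_miou, reverse=True)
        while len(self.entries) > self.top_k:
            dropped = self.entries.pop()
            Path(dropped.path).unlink(missing_ok=True)
        return True

    def best(self):
        return self.entries[0] if self.entries else None


# ---------------------------------------------------------------------------
# data access
# ---------------------------------------------------------------------------

def load_arrays(manifest: DatasetManifest, indices=None, threads=1):
    """Decode manifest pairs into ((M,3,H,W) float32, (M,H,W) int64).

    PNG decoding is fanned out over ``threads`` reader threads.
    """
    pairs = manifest.pairs
    if indices is not None:
        pairs = [manifest.pairs[i] for i in indices]
    if not pairs:
        raise ValueError("empty split: nothing to load")
    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            loaded = list(pool.map(lambda p: load_pair(*p), pairs))
    else:
        loaded = [load_pair(*p) for p in pairs]
    images = np.stack([im for im, _ in loaded])
    masks = np.stack([mk for _, mk in loaded])
    return images, masks


def _iter_batches(n, batch_size, rng=None):
    order = np.arange(n) if rng is None else rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


# ---------------------------------------------------------------------------
# core loops
# ---------------------------------------------------------------------------

def train_step(model, optimizer, images, masks, loss_config):
    """One focal-loss optimization step; returns (loss value, logits)."""
    optimizer.zero_grad()
    logits = model(nn.as_tensor(images))
    loss = focal_loss(logits, masks, loss_config)
    if not math.isfinite(loss.item()):
        raise RuntimeError(
            f"non-finite loss ({loss.item()}): diverged or bad input")
    loss.backward()
    optimizer.step()
    return loss.item(), logits


def predict(model, images, batch_size=8):
    """Per-pixel argmax labels for a stack of images (inference mode)."""
    model.eval()
    outputs = []
    for idx in _iter_batches(len(images), batch_size):
        outputs.append(model.predict(images[idx]))
    return np.concatenate(outputs, axis=0)


def evaluate_split(model, images, masks, num_classes, batch_size=8):
    """Global-confusion metrics of a model over one split."""
    preds = predict(model, images, batch_size)
    cm = confusion_matrix(preds, masks, num_classes - 1)
    return MetricsReport.from_confusion(cm)


def train(model_config: ModelConfig, train_config: TrainConfig,
          manifest: DatasetManifest, split: SplitSpec, out_dir,
          max_steps=None):
    """Run the full protocol; returns (model, CheckpointSet, log rows).

    ``max_steps`` optionally caps total optimization steps (smoke runs).
    The run directory receives the per-epoch CSV log, checkpoints and the
    checkpoint index.
    """
    train_config.validate()
    model_config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(manifest) == 0:
        raise ValueError("empty manifest")

    threads = max(1, train_config.reader_threads)
    tr_images, tr_masks = load_arrays(manifest, split.train_indices, threads)
    va_images, va_masks = load_arrays(manifest, split.val_indices, threads)

    model = build_model(model_config, seed=model_config.seed)
    optimizer = nn.AdamW(model.parameters(), lr=train_config.lr,
                         weight_decay=train_config.weight_decay)
    scheduler = nn.ReduceLROnPlateau(
        optimizer, mode="max", factor=train_config.plateau_factor,
        patience=train_config.plateau_patience, min_lr=train_config.min_lr)
    loss_config = FocalLossConfig(gamma=train_config.gamma,
                                  alpha=train_config.alpha)
    checkpoints = CheckpointSet(top_k=train_config.top_k_checkpoints)
    rng = np.random.default_rng(train_config.seed)

    log_rows = []
    steps = 0
    for epoch in range(1, train_config.epochs + 1):
        model.train()
        losses = []
        for batch in _iter_batches(len(tr_images), train_config.batch_size, rng):
            loss_value, _ = train_step(model, optimizer, tr_images[batch],
                                       tr_masks[batch], loss_config)
            losses.append(loss_value)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                break
        row = {"epoch": epoch, "loss": float(np.mean(losses)),
               "lr": optimizer.lr, "val_miou": ""}
        if epoch % train_config.val_every == 0:
            report = evaluate_split(model, va_images, va_masks,
                                    model_config.num_classes,
                                    train_config.batch_size)
            val_miou = report.means["miou"]
            checkpoints.offer(val_miou, epoch, model.state_dict(),
                              out_dir / "checkpoints")
            scheduler.step(val_miou)
            row["val_miou"] = val_miou
        log_rows.append(row)
        if max_steps is not None and steps >= max_steps:
            break

    if not checkpoints.entries:  # no validation happened before the cap
        checkpoints.offer(float("nan"), train_config.epochs,
                          model.state_dict(), out_dir / "checkpoints")
    _write_log(out_dir / "log.csv", log_rows)
    _write_index(out_dir / "checkpoints.csv", checkpoints)
    return model, checkpoints, log_rows


def evaluate(checkpoints: CheckpointSet, manifest: DatasetManifest,
             indices, model_config: ModelConfig, batch_size=8, threads=1):
    """Metrics per retained checkpoint plus their arithmetic mean.

    Returns a dict with ``per_checkpoint`` (list of MetricsReport means) and
    ``mean`` (metric-wise average across checkpoints).
    """
    if not checkpoints.entries:
        raise ValueError("no checkpoints to evaluate")
    images, masks = load_arrays(manifest, indices, threads)
    model = build_model(model_config)
    per_ckpt = []
    for entry in checkpoints.entries:
        if not Path(entry.path).exists():
            raise FileNotFoundError(entry.path)
        model.load_state_dict(nn.load_state(entry.path))
        report = evaluate_split(model, images, masks,
                                model_config.num_classes, batch_size)
        per_ckpt.append({"epoch": entry.epoch, "val_miou": entry.val_miou,
                         **report.means})
    keys = ("precision", "recall", "f1", "miou")
    averaged = {k: float(np.mean([r[k] for r in per_ckpt])) for k in keys}
    return {"per_checkpoint": per_ckpt, "mean": averaged}


def overfit(model, images, masks, loss_config=None, max_steps=300,
            target_miou=None, lr=1e-3, weight_decay=1e-2, log_every=5):
    """Full-batch overfitting run used by smoke checks and the worked example.

    Trains up to ``max_steps`` steps on the given images, computing the
    training mIoU from the forward logits every ``log_every`` steps, and
    stops early once ``target_miou`` is reached.  Returns the history list
    of (step, loss, train_miou or None).
    """
    loss_config = loss_config or FocalLossConfig()
    optimizer = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
    k = model.config.num_classes - 1
    history = []
    model.train()
    for step in range(1, max_steps + 1):
        loss_value, logits = train_step(model, optimizer, images, masks,
                                        loss_config)
        miou = None
        if step % log_every == 0 or step == max_steps:
            preds = np.argmax(logits.data, axis=1)
            miou = mean_iou(confusion_matrix(preds, masks, k))
        history.append((step, loss_value, miou))
        if target_miou is not None and miou is not None and miou >= target_miou:
            break
    return history


def _write_log(path, rows):
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "loss", "lr",
                                                "val_miou"])
        writer.writeheader()
        writer.writerows(rows)


def _write_index(path, checkpoints: CheckpointSet):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["rank", "epoch", "val_miou", "path"])
        for rank, e in enumerate(checkpoints.entries, 1):
            writer.writerow([rank, e.epoch, f"{e.val_miou:.6f}", e.path])
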