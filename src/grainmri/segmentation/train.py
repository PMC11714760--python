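"""Training, model selection, checkpointing, and sliding-window prediction."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import ConfigError, StandardizationError, ValidationError
from ..io import LabelVolume, N_CLASSES
from .dataset import SliceSample, TrainConfig, augment_sample, standardize_volume
from .metrics import dice_score
from .nn import Adam, UNet2D, softmax_cross_entropy


@dataclass
class SegmenterModel:
    """A trained slice segmenter plus its architecture descriptor."""

    net: UNet2D
    context_depth: int = 0
    normalization: str = "volume_zscore"

    @property
    def descriptor(self) -> dict:
        return {
            "type": "unet2d",
            "levels": 3,
            "channels": self.net.channels,
            "in_channels": self.net.in_channels,
            "n_classes": self.net.n_classes,
            "context_depth": self.context_depth,
            "normalization": self.normalization,
        }

    def save(self, path):
        """Single-file checkpoint: architecture descriptor + parameters."""
        arrays = {}
        for i, (w, b) in enumerate(self.net.get_weights()):
            arrays[f"W{i}"] = w
            arrays[f"b{i}"] = b
        np.savez_compressed(path, descriptor=json.dumps(self.descriptor), **arrays)

    @classmethod
    def load(cls, path) -> "SegmenterModel":
        with np.load(path, allow_pickle=False) as npz:
            desc = json.loads(str(npz["descriptor"]))
            net = UNet2D(desc["in_channels"], n_classes=desc["n_classes"],
                         channels=desc["channels"])
            n = len(net.convs)
            net.set_weights([(npz[f"W{i}"], npz[f"b{i}"]) for i in range(n)])
        return cls(net=net, context_depth=desc["context_depth"],
                   normalization=desc["normalization"])


def _batch(samples, idx):
    x = np.stack([samples[i].stack for i in idx]).astype(np.float32)
    y = np.stack([samples[i].target for i in idx])
    return x, y


def _evaluate(net, samples, batch_size, class_weights=None):
    """Mean loss and mean tissue Dice over a sample set."""
    losses, dices = [], []
    for start in range(0, len(samples), batch_size):
        idx = range(start, min(start + batch_size, len(samples)))
        x, y = _batch(samples, idx)
        logits = net.forward(x, train=False)
        loss, _ = softmax_cross_entropy(logits, y, class_weights)
        losses.append(loss * len(x))
        pred = logits.argmax(axis=1)
        for p, t in zip(pred, y):
            dices.append(dice_score(p, t)["mean"])
    return float(np.sum(losses) / len(samples)), float(np.mean(dices))


def train_segmenter(train_samples, val_samples, cfg: TrainConfig):
    """Train the compact U-Net; return the best-validation-loss model and a log.

    The session runs ``cfg.epochs`` passes over the training set with Adam
    and (optionally weighted) cross-entropy; the returned parameter state is
    the one minimizing validation loss across epochs.  The log is a
    DataFrame with per-epoch train/val loss and validation Dice.
    """
    if not train_samples:
        raise ConfigError("training set is empty")
    if not val_samples:
        raise ConfigError("validation set is empty")
    train_ids = {(s.volume_id, s.slice_index) for s in train_samples}
    val_ids = {(s.volume_id, s.slice_index) for s in val_samples}
    if train_ids & val_ids:
        raise ConfigError("train and validation sets overlap")
    k = train_samples[0].k
    if k != cfg.context_depth:
        raise ConfigError(f"sample context depth {k} != config context depth {cfg.context_depth}")

    rng = np.random.default_rng(cfg.seed)
    net = UNet2D(2 * k + 1, n_classes=N_CLASSES, channels=cfg.channels,
                 seed=int(rng.integers(2**31)))
    opt = Adam(net, lr=cfg.learning_rate)
    use_aug = any(cfg.augment.get(key) for key in TrainConfig.AUG_KEYS)

    best = (np.inf, net.get_weights())
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_samples))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if use_aug:
                batch = [augment_sample(train_samples[i], cfg, int(rng.integers(2**31)))
                         for i in idx]
                x = np.stack([s.stack for s in batch]).astype(np.float32)
                y = np.stack([s.target for s in batch])
            else:
                x, y = _batch(train_samples, idx)
            logits = net.forward(x, train=True)
            loss, dlogits = softmax_cross_entropy(logits, y, cfg.class_weights)
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        val_loss, val_dice = _evaluate(net, val_samples, cfg.batch_size, cfg.class_weights)
        rows.append({"epoch": epoch, "train_loss": epoch_loss / len(train_samples),
                     "val_loss": val_loss, "val_dice": val_dice})
        if val_loss < best[0]:
            best = (val_loss, net.get_weights())

    net.set_weights(best[1])
    model = SegmenterModel(net=net, context_depth=k)
    return model, pd.DataFrame(rows)


def predict_volume(model: SegmenterModel, vol, k: int | None = None,
                   batch_size: int = 16) -> LabelVolume:
    """Segment a whole volume with the sliding-window slice model.

    The volume is standardized (constant volumes pass through as zeros),
    each cross-section is predicted from its 2k+1-slice stack, and per-pixel
    argmax over the 5 class scores assembles the 3D label volume.
    """
    if k is None:
        k = model.context_depth
    if k != model.context_depth:
        raise ConfigError(f"model was trained with context depth {model.context_depth}, got {k}")
    h, w = vol.data.shape[1:]
    if h % 4 or w % 4:
        raise ValidationError(f"cross-section {h}x{w} not divisible by 4 (three-level model)")
    try:
        svol = standardize_volume(vol)
    except StandardizationError:
        # constant volume carries no signal: all background by definition
        return LabelVolume(np.zeros(vol.data.shape, dtype=np.uint8),
                           voxel_size=vol.voxel_size, source_id=vol.source_id)
    data = svol.data
    n = data.shape[0]
    out = np.empty((n, h, w), dtype=np.uint8)
    for start in range(0, n, batch_size):
        stop = min(start + batch_size, n)
        stacks = []
        for i in range(start, stop):
            idx = np.clip(np.arange(i - k, i + k + 1), 0, n - 1)
            stacks.append(data[idx])
        logits = model.net.forward(np.stack(stacks).astype(np.float32), train=False)
        out[start:stop] = logits.argmax(axis=1).astype(np.uint8)
    return LabelVolume(out, voxel_size=vol.voxel_size, source_id=vol.source_id)
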