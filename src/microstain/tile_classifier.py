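"""Model 1: the tile-level convolutional classifier.

The network is a pluggable backbone (classification head removed) followed by
global average pooling and a single sigmoid unit, trained in two phases:

* phase 1 — one epoch with every convolutional layer frozen (head only);
* phase 2 — the last two convolutional blocks unfrozen, ten epochs at a lower
  learning rate;

with a class-weighted binary cross-entropy (minority class up-weighted),
train-time augmentation (flips, rotation, channel shifts) and restoration of
the weights from the epoch with the best validation AUC (the phase-1 epoch
competes). The stock backbone is a small four-block CNN taking 64-px tiles;
larger pretrained backbones satisfy the same contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize, rotate
from sklearn.metrics import roc_auc_score

from . import nn
from .tiling import TileSet, tile_pixels

__all__ = [
    "BackboneSpec",
    "TrainingSchedule",
    "TilePredictionSeries",
    "build_model",
    "class_weights",
    "augment_batch",
    "train",
    "predict_tiles",
    "predict_array",
    "tiles_to_array",
    "StainFractionScorer",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture contract for the convolutional feature extractor."""

    name: str = "smallcnn4"
    conv_blocks: tuple[str, ...] = ("block1", "block2", "block3", "block4")
    channels: tuple[int, ...] = (8, 16, 32, 64)
    pretrained: bool = False
    input_size: int = 64

    def __post_init__(self):
        if len(self.conv_blocks) < 2:
            raise ValueError("backbone needs >= 2 blocks ('last two blocks' "
                             "must be meaningful)")
        if len(self.channels) != len(self.conv_blocks):
            raise ValueError("one channel width per block required")


@dataclass(frozen=True)
class TrainingSchedule:
    """Two-phase transfer-style schedule.

    The stated learning rates (1e-4 then 1e-5) are fine-tuning rates for a
    pretrained backbone; :meth:`from_scratch` returns the same structure with
    rates suited to a randomly initialised small CNN.
    """

    phase1_epochs: int = 1
    phase1_lr: float = 1e-4
    phase2_epochs: int = 10
    phase2_lr: float = 1e-5
    batch_size: int = 64
    unfrozen_blocks_phase2: int = 2
    augmentation: bool = True
    rotation_range: float = 90.0     # degrees, uniform in +/- range
    channel_shift: float = 0.1       # uniform per-channel shift in +/- range

    def __post_init__(self):
        if self.phase1_lr <= 0 or self.phase2_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.phase1_epochs < 1 or self.phase2_epochs < 1:
            raise ValueError("epoch counts must be >= 1")

    @classmethod
    def from_scratch(cls, **overrides) -> "TrainingSchedule":
        """Preset for a randomly initialised backbone: same two-phase
        structure, but hotter rates, smaller batches (more optimiser steps on
        small tile sets) and every block unfrozen in phase 2 — freezing
        random, untrained blocks would serve no purpose."""
        kw = dict(phase1_lr=1e-2, phase2_lr=3e-3, batch_size=16,
                  unfrozen_blocks_phase2=4)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class TilePredictionSeries:
    """Ordered per-tile ABMR probabilities of one slide, in tile export order."""

    patient_id: str
    marker: str
    probabilities: np.ndarray

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.size and not (
            (self.probabilities >= 0).all() and (self.probabilities <= 1).all()
        ):
            raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.probabilities.size


def build_model(backbone: BackboneSpec = BackboneSpec(), seed: int = 0,
                dtype=np.float32) -> nn.Sequential:
    """Backbone (head removed) -> global average pooling -> 1 sigmoid unit.

    Each block is two 3x3 conv+ReLU layers followed by 2x2 max pooling. The
    returned model outputs the logit; apply :func:`microstain.nn.sigmoid` for
    the probability. Identical seeds give identical initial weights.
    """
    if len(backbone.conv_blocks) < 2:
        raise ValueError("backbone needs >= 2 blocks")
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    c_in = 3
    for bname, c_out in zip(backbone.conv_blocks, backbone.channels):
        layers.append(nn.Conv2D(f"{bname}_conv1", c_in, c_out, rng=rng, dtype=dtype))
        layers.append(nn.ReLU(f"{bname}_relu1"))
        layers.append(nn.Conv2D(f"{bname}_conv2", c_out, c_out, rng=rng, dtype=dtype))
        layers.append(nn.ReLU(f"{bname}_relu2"))
        layers.append(nn.MaxPool2(f"{bname}_pool"))
        c_in = c_out
    layers.append(nn.GlobalAvgPool("gap"))
    layers.append(nn.Dense("head", c_in, 1, rng=rng, dtype=dtype))
    model = nn.Sequential(layers)
    model.backbone = backbone  # type: ignore[attr-defined]
    return model


def last_conv_layer(model: nn.Sequential) -> str:
    convs = [l.name for l in model.layers if isinstance(l, nn.Conv2D)]
    if not convs:
        raise ValueError("model has no convolutional layer")
    return convs[-1]


def class_weights(labels: Sequence[int]) -> dict[int, float]:
    """Inverse-frequency class weights w_c = N / (2 * N_c).

    The under-represented class gets the larger weight, so its
    misclassifications cost more; balanced data gives (1.0, 1.0).
    """
    y = np.asarray(labels).astype(int)
    counts = {c: int((y == c).sum()) for c in (0, 1)}
    if counts[0] == 0 or counts[1] == 0:
        raise ValueError("both classes must be present to compute class weights")
    n = y.size
    return {c: n / (2.0 * counts[c]) for c in (0, 1)}


def augment_batch(x: np.ndarray, rng: np.random.Generator,
                  schedule: TrainingSchedule) -> np.ndarray:
    """Random flips, rotation and per-channel intensity shifts (train only)."""
    out = x.copy()
    for i in range(out.shape[0]):
        img = out[i]
        if rng.uniform() < 0.5:
            img = img[:, ::-1]
        if rng.uniform() < 0.5:
            img = img[::-1, :]
        angle = rng.uniform(-schedule.rotation_range, schedule.rotation_range)
        img = rotate(img, angle, mode="reflect", preserve_range=True)
        shift = rng.uniform(-schedule.channel_shift, schedule.channel_shift, size=3)
        img = np.clip(img + shift[None, None, :], 0.0, 1.0)
        out[i] = img.astype(out.dtype)
    return out


def _set_phase_trainability(model: nn.Sequential, phase: int,
                            schedule: TrainingSchedule) -> None:
    backbone: BackboneSpec = model.backbone  # type: ignore[attr-defined]
    if phase == 1:
        unfrozen_blocks: set[str] = set()
    else:
        unfrozen_blocks = set(backbone.conv_blocks[-schedule.unfrozen_blocks_phase2:])
    for layer in model.layers:
        if isinstance(layer, nn.Conv2D):
            block = layer.name.rsplit("_", 1)[0]
            layer.trainable = block in unfrozen_blocks
        elif isinstance(layer, nn.Dense):
            layer.trainable = True


@dataclass
class TrainingHistory:
    records: list[dict] = field(default_factory=list)
    best_epoch: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["epoch", "phase", "train_loss", "val_auc"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def train(model: nn.Sequential, x_train: np.ndarray, y_train: Sequence[int],
          x_val: np.ndarray, y_val: Sequence[int],
          schedule: TrainingSchedule = TrainingSchedule(), seed: int = 0,
          metric_fn: Callable[[np.ndarray, np.ndarray], float] | None = None,
          ) -> TrainingHistory:
    """Run the two-phase schedule in place; restore the best-val-AUC weights.

    ``metric_fn(y_true, scores)`` defaults to the ROC AUC; the epoch (from
    either phase) maximising it on the validation set supplies the final
    weights. Augmentation touches only training batches. Deterministic for a
    fixed seed.
    """
    y_train = np.asarray(y_train).astype(int)
    y_val = np.asarray(y_val).astype(int)
    if x_train.shape[0] == 0:
        raise ValueError("training set is empty")
    if len(np.unique(y_val)) < 2:
        raise ValueError("validation set must contain both classes (AUC undefined)")
    metric_fn = metric_fn or (lambda yt, s: roc_auc_score(yt, s))
    weights = class_weights(y_train)
    w_train = np.where(y_train == 1, weights[1], weights[0])
    rng = np.random.default_rng(seed)

    history = TrainingHistory()
    best = (-np.inf, None)
    epoch_counter = 0
    for phase, epochs, lr in ((1, schedule.phase1_epochs, schedule.phase1_lr),
                              (2, schedule.phase2_epochs, schedule.phase2_lr)):
        _set_phase_trainability(model, phase, schedule)
        opt = nn.Adam(model, lr=lr)
        for _ in range(epochs):
            epoch_counter += 1
            order = rng.permutation(x_train.shape[0])
            losses = []
            for start in range(0, len(order), schedule.batch_size):
                idx = order[start:start + schedule.batch_size]
                xb = x_train[idx]
                if schedule.augmentation:
                    xb = augment_batch(xb, rng, schedule)
                logits = model.forward(xb).ravel()
                loss, dz = nn.weighted_bce_with_logits(logits, y_train[idx],
                                                       w_train[idx])
                model.backward(dz.reshape(-1, 1))
                opt.step()
                losses.append(loss)
            val_scores = predict_array(model, x_val)
            val_auc = float(metric_fn(y_val, val_scores))
            history.records.append({"epoch": epoch_counter, "phase": phase,
                                    "train_loss": float(np.mean(losses)),
                                    "val_auc": val_auc})
            if val_auc > best[0]:
                best = (val_auc, model.get_weights())
                history.best_epoch = epoch_counter
    if best[1] is not None:
        model.set_weights(best[1])
    return history


def predict_array(model: nn.Sequential, x: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    """Sigmoid probabilities for an array of tiles (batch-size invariant)."""
    if x.shape[0] == 0:
        return np.empty(0, dtype=np.float64)
    out = []
    for start in range(0, x.shape[0], batch_size):
        logits = model.forward(x[start:start + batch_size])
        out.append(nn.sigmoid(logits.ravel()))
    return np.concatenate(out)


def tiles_to_array(tileset: TileSet, input_size: int | None = None) -> np.ndarray:
    """Stack a TileSet's pixels, bilinearly rescaled to the model input size."""
    if len(tileset) == 0:
        size = input_size or tileset.tile_size
        return np.empty((0, size, size, 3), dtype=np.float32)
    crops = [tile_pixels(tileset, t) for t in tileset]
    if input_size is not None and input_size != tileset.tile_size:
        crops = [resize(c, (input_size, input_size, 3), order=1,
                        preserve_range=True, anti_aliasing=True) for c in crops]
    return np.stack(crops).astype(np.float32)


def predict_tiles(model: nn.Sequential, tileset: TileSet,
                  batch_size: int = 64) -> TilePredictionSeries:
    """One probability per tile, in export order."""
    backbone: BackboneSpec | None = getattr(model, "backbone", None)
    input_size = backbone.input_size if backbone else None
    x = tiles_to_array(tileset, input_size)
    return TilePredictionSeries(patient_id=tileset.patient_id,
                                marker=tileset.marker,
                                probabilities=predict_array(model, x, batch_size))


def save_model(model: nn.Sequential, path) -> None:
    """Serialize weights plus the backbone contract to one ``.npz`` file."""
    backbone: BackboneSpec = model.backbone  # type: ignore[attr-defined]
    meta = {"name": backbone.name, "conv_blocks": list(backbone.conv_blocks),
            "channels": list(backbone.channels), "pretrained": backbone.pretrained,
            "input_size": backbone.input_size}
    arrays = {f"{l.name}/{k}": v for l in model.layers for k, v in l.params.items()}
    np.savez(path, __backbone__=np.array(json.dumps(meta)), **arrays)


def load_model(path) -> nn.Sequential:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__backbone__"]))
        spec = BackboneSpec(name=meta["name"],
                            conv_blocks=tuple(meta["conv_blocks"]),
                            channels=tuple(meta["channels"]),
                            pretrained=meta["pretrained"],
                            input_size=meta["input_size"])
        model = build_model(spec)
        for l in model.layers:
            for k in l.params:
                l.params[k] = np.asarray(data[f"{l.name}/{k}"])
    return model


class StainFractionScorer:
    """Deterministic non-neural baseline: scores a tile by its brown-pixel
    fraction squashed through a logistic. Useful as a fast stand-in tile
    scorer in plumbing tests and as a sanity baseline."""

    def __init__(self, threshold: float = 0.05, gain: float = 30.0,
                 midpoint: float = 0.05):
        self.threshold = threshold
        self.gain = gain
        self.midpoint = midpoint

    def predict_tiles(self, tileset: TileSet) -> TilePredictionSeries:
        from .synthetic_data import stained_fraction
        probs = [
            float(nn.sigmoid(np.array(
                self.gain * (stained_fraction(tile_pixels(tileset, t),
                                              self.threshold) - self.midpoint))))
            for t in tileset
        ]
        return TilePredictionSeries(tileset.patient_id, tileset.marker,
                                    np.asarray(probs))
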