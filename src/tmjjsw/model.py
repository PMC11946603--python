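"""Residual U-Net training and inference harness.

The segmentation network is a 2D residual U-Net with a single-channel
input and a four-channel output (background, MC, JS, GF), feature
channels [16, 32, 64, 128] with stride-2 downsampling, 16 residual
subunits per block, instance normalization, PReLU activation and
dropout 0.3. Training uses soft Dice loss on softmax probabilities
(background excluded by default), Adam at 1e-3 with a
reduce-on-plateau schedule, batch size 2, and per-epoch checkpoint
selection by validation mean Dice. Several independently seeded runs
can be ensembled by averaging their softmax probabilities.

Everything runs on the CPU in float64; the full-size configuration is
practical for inference and parameter accounting, while training-based
tests use toy configurations on small phantoms.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nn
from .datamodel import FOREGROUND_CLASSES, LabelMask, UltrasoundImage
from .postprocess import ComponentFilter


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the residual U-Net (defaults: the full-size model)."""

    in_channels: int = 1
    out_channels: int = 4
    feature_channels: tuple[int, ...] = (16, 32, 64, 128)
    stride: int = 2
    residual_units_per_block: int = 16
    kernel_size: int = 3
    dropout: float = 0.3

    def __post_init__(self):
        if self.in_channels != 1:
            raise ValueError("the model takes a single-channel (grayscale) input")
        if self.out_channels != 4:
            raise ValueError("out_channels must equal the number of classes (4)")
        ch = tuple(self.feature_channels)
        if len(ch) < 2 or any(b <= a for a, b in zip(ch, ch[1:])):
            raise ValueError(f"feature_channels must be strictly increasing, got {ch}")
        if self.stride < 2:
            raise ValueError("stride must be >= 2")

    @property
    def strides(self) -> tuple[int, ...]:
        return (self.stride,) * (len(self.feature_channels) - 1)

    @property
    def spatial_divisor(self) -> int:
        return int(np.prod(self.strides))


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe (defaults: the full training protocol)."""

    epochs: int = 150
    batch_size: int = 2
    initial_lr: float = 1e-3
    scheduler_factor: float = 0.5
    scheduler_patience: int = 10
    include_background: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("learning rate must be > 0")


@dataclass
class SegmentationResult:
    """Per-pixel class probabilities and their argmax label mask."""

    class_probabilities: np.ndarray  # (C, H, W), rows sum to 1 per pixel
    label_mask: np.ndarray           # (H, W) integer classes


@dataclass
class TrainedRun:
    """A trained network with its best-checkpoint weights and epoch log."""

    model: nn.ResidualUNet
    history: pd.DataFrame = field(repr=False)
    best_epoch: int = -1
    best_val_dice: float = float("nan")
    config: ModelConfig | None = None


def build_model(config: ModelConfig, seed: int = 0) -> nn.ResidualUNet:
    """Instantiate the network described by ``config``."""
    return nn.ResidualUNet(
        in_channels=config.in_channels,
        out_channels=config.out_channels,
        channels=config.feature_channels,
        strides=config.strides,
        num_res_units=config.residual_units_per_block,
        kernel_size=config.kernel_size,
        dropout=config.dropout,
        seed=seed,
    )


def soft_dice_loss(probabilities: np.ndarray, reference_onehot: np.ndarray,
                   include_background: bool = False, eps: float = 1e-5) -> float:
    """Soft Dice loss of softmax probabilities against a one-hot reference."""
    loss, _ = nn.soft_dice(probabilities, reference_onehot, include_background, eps)
    return loss


def _as_input_array(image) -> np.ndarray:
    """Image -> float64 (H, W) in [0, 1]."""
    px = image.pixels if isinstance(image, UltrasoundImage) else np.asarray(image)
    px = px.astype(np.float64)
    if px.max() > 1.0:
        px = px / 255.0
    return px


def _mask_array(mask) -> np.ndarray:
    return mask.labels if isinstance(mask, LabelMask) else np.asarray(mask)


def _foreground_mean_dice(pred: np.ndarray, ref: np.ndarray) -> float:
    scores = []
    for code in FOREGROUND_CLASSES:
        p, g = pred == code, ref == code
        denom = p.sum() + g.sum()
        scores.append(1.0 if denom == 0 else 2.0 * np.logical_and(p, g).sum() / denom)
    return float(np.mean(scores))


def train(model: nn.ResidualUNet, train_set: Sequence[tuple], val_set: Sequence[tuple],
          tc: TrainConfig) -> TrainedRun:
    """Train ``model`` on (image, mask) pairs; select the best epoch by val Dice.

    ``train_set`` / ``val_set`` are sequences of pairs: an image (2D
    array or :class:`UltrasoundImage`, normalized internally to [0, 1])
    and an integer label mask of the same shape.
    """
    if not train_set or not val_set:
        raise ValueError("train_set and val_set must be non-empty")
    xs = np.stack([_as_input_array(im) for im, _ in train_set])[:, None]
    ys = np.stack([_mask_array(m) for _, m in train_set])
    vx = np.stack([_as_input_array(im) for im, _ in val_set])[:, None]
    vy = np.stack([_mask_array(m) for _, m in val_set])

    rng = np.random.default_rng(tc.seed)
    opt = nn.Adam(model.params(), lr=tc.initial_lr)
    sched = nn.ReduceLROnPlateau(opt, "max", tc.scheduler_factor, tc.scheduler_patience)
    n_classes = model.out_channels

    rows = []
    best_state, best_dice, best_epoch = None, -np.inf, -1
    for epoch in range(tc.epochs):
        order = rng.permutation(len(xs))
        losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start:start + tc.batch_size]
            opt.zero_grad()
            logits = model.forward(xs[idx], training=True)
            probs = nn.softmax(logits)
            loss, dprobs = nn.soft_dice(probs, nn.one_hot(ys[idx], n_classes),
                                        tc.include_background)
            model.backward(nn.softmax_backward(probs, dprobs))
            opt.step()
            losses.append(loss)
        val_dice = float(np.mean([
            _foreground_mean_dice(
                np.argmax(model.forward(vx[i:i + 1], training=False), axis=1)[0], vy[i])
            for i in range(len(vx))]))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_mean_dice": val_dice, "lr": opt.lr})
        if val_dice > best_dice:
            best_dice, best_epoch = val_dice, epoch
            best_state = model.get_state()
        sched.step(val_dice)
    model.set_state(best_state)
    history = pd.DataFrame(rows)
    history.attrs["lr_reductions"] = sched.reductions
    return TrainedRun(model=model, history=history, best_epoch=best_epoch,
                      best_val_dice=best_dice)


# ------------------------------------------------------------ inference

def _pad_to_divisor(x: np.ndarray, divisor: int) -> tuple[np.ndarray, tuple]:
    h, w = x.shape
    ph, pw = (-h) % divisor, (-w) % divisor
    top, left = ph // 2, pw // 2
    padded = np.pad(x, ((top, ph - top), (left, pw - left)))
    return padded, (top, top + h, left, left + w)


def _run_model(run) -> nn.ResidualUNet:
    if isinstance(run, TrainedRun):
        return run.model
    if isinstance(run, ResidualUNetSegmenter):
        return run.run_.model
    if isinstance(run, nn.ResidualUNet):
        return run
    raise TypeError(f"cannot interpret {type(run).__name__} as a trained run")


def ensemble_predict(runs: Sequence, image) -> SegmentationResult:
    """Mean-softmax ensemble of one or more trained runs on one image."""
    if not runs:
        raise ValueError("need at least one trained run")
    models = [_run_model(r) for r in runs]
    shapes = {(m.channels, m.strides, m.in_channels, m.out_channels) for m in models}
    if len(shapes) > 1:
        raise ValueError("ensembled runs must share one architecture")
    x = _as_input_array(image)
    divisor = int(np.prod(models[0].strides))
    padded, (r0, r1, c0, c1) = _pad_to_divisor(x, divisor)
    probs = np.mean([nn.softmax(m.forward(padded[None, None], training=False))[0]
                     for m in models], axis=0)
    probs = probs[:, r0:r1, c0:c1]
    return SegmentationResult(class_probabilities=probs,
                              label_mask=np.argmax(probs, axis=0).astype(np.uint8))


def predict_case(runs: Sequence, image, spacing_mm: tuple[float, float] | None = None,
                 cc_threshold: float = 0.60, connectivity: int = 8,
                 postprocess: bool = True) -> LabelMask:
    """Ensemble → argmax → connected-component filtering for one case."""
    result = ensemble_predict(runs if isinstance(runs, (list, tuple)) else [runs], image)
    if spacing_mm is None:
        spacing_mm = image.spacing_mm if isinstance(image, UltrasoundImage) else (1.0, 1.0)
    mask = LabelMask(labels=result.label_mask, spacing_mm=spacing_mm,
                     id=getattr(image, "id", ""))
    if postprocess:
        mask = ComponentFilter(cc_threshold, connectivity).transform(mask)
    return mask


class ResidualUNetSegmenter(BaseEstimator):
    """Scikit-learn style estimator wrapping the residual U-Net.

    Parameters mirror :class:`ModelConfig` and :class:`TrainConfig`;
    defaults are the full-size recipe, so tests and examples pass toy
    values (small ``feature_channels``, few ``epochs``).

    Attributes (after :meth:`fit`)
    ------------------------------
    run_ : TrainedRun
        Trained network, best-epoch weights restored.
    history_ : pandas.DataFrame
        Per-epoch train loss, validation mean Dice and learning rate.
    n_parameters_ : int
        Trainable parameter count of the built network.
    """

    def __init__(self, feature_channels=(16, 32, 64, 128), residual_units_per_block=16,
                 kernel_size=3, dropout=0.3, epochs=150, batch_size=2, initial_lr=1e-3,
                 scheduler_factor=0.5, scheduler_patience=10, include_background=False,
                 validation_fraction=0.2, random_state=0):
        self.feature_channels = feature_channels
        self.residual_units_per_block = residual_units_per_block
        self.kernel_size = kernel_size
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.scheduler_factor = scheduler_factor
        self.scheduler_patience = scheduler_patience
        self.include_background = include_background
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _configs(self) -> tuple[ModelConfig, TrainConfig]:
        mc = ModelConfig(feature_channels=tuple(self.feature_channels),
                         residual_units_per_block=self.residual_units_per_block,
                         kernel_size=self.kernel_size, dropout=self.dropout)
        tc = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                         initial_lr=self.initial_lr, scheduler_factor=self.scheduler_factor,
                         scheduler_patience=self.scheduler_patience,
                         include_background=self.include_background, seed=self.random_state)
        return mc, tc

    def fit(self, X, y, X_val=None, y_val=None):
        """Fit on images ``X`` and integer masks ``y``.

        Without an explicit validation set, the trailing
        ``validation_fraction`` of the training pairs is held out for
        checkpoint selection and the lr schedule.
        """
        pairs = list(zip(X, y))
        if X_val is not None:
            val_pairs = list(zip(X_val, y_val))
        else:
            n_val = max(1, int(len(pairs) * self.validation_fraction))
            if len(pairs) <= n_val:
                raise ValueError("not enough samples to hold out a validation split")
            pairs, val_pairs = pairs[:-n_val], pairs[-n_val:]
        mc, tc = self._configs()
        model = build_model(mc, seed=self.random_state)
        self.n_parameters_ = model.n_parameters()
        self.config_ = mc
        self.run_ = train(model, pairs, val_pairs, tc)
        self.history_ = self.run_.history
        self.best_val_dice_ = self.run_.best_val_dice
        return self

    def predict(self, X) -> list[np.ndarray]:
        """Argmax label mask for each image (no postprocessing)."""
        return [ensemble_predict([self], im).label_mask for im in X]

    def predict_proba(self, X) -> list[np.ndarray]:
        """Softmax class-probability maps, shape (4, H, W) each."""
        return [ensemble_predict([self], im).class_probabilities for im in X]

    def score(self, X, y) -> float:
        """Mean foreground Dice over cases."""
        preds = self.predict(X)
        return float(np.mean([_foreground_mean_dice(p, _mask_array(g))
                              for p, g in zip(preds, y)]))

    def describe(self) -> dict:
        mc, tc = self._configs()
        return {"model": asdict(mc), "training": asdict(tc)}


def clone_run(run: TrainedRun) -> TrainedRun:
    """Deep-copy a trained run (weights included)."""
    return copy.deepcopy(run)


def save_run(run: TrainedRun, directory) -> None:
    """Persist a trained run: ``weights.npz`` plus a JSON config sidecar."""
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model = _run_model(run)
    np.savez(directory / "weights.npz",
             **{f"param_{i}": p.value for i, p in enumerate(model.params())})
    meta = {
        "in_channels": model.in_channels,
        "out_channels": model.out_channels,
        "feature_channels": list(model.channels),
        "residual_units_per_block": model.num_res_units,
        "kernel_size": model.kernel_size,
        "dropout": model.dropout,
        "best_epoch": getattr(run, "best_epoch", -1),
        "best_val_dice": getattr(run, "best_val_dice", None),
    }
    (directory / "config.json").write_text(json.dumps(meta, indent=2))
    history = getattr(run, "history", None)
    if history is not None:
        history.to_csv(directory / "history.csv", index=False)


def load_run(directory) -> TrainedRun:
    """Load a run saved by :func:`save_run`."""
    import json
    from pathlib import Path

    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    config = ModelConfig(
        feature_channels=tuple(meta["feature_channels"]),
        residual_units_per_block=meta["residual_units_per_block"],
        kernel_size=meta["kernel_size"],
        dropout=meta["dropout"],
    )
    model = build_model(config)
    with np.load(directory / "weights.npz") as weights:
        model.set_state([weights[f"param_{i}"] for i in range(len(model.params()))])
    hist_path = directory / "history.csv"
    history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
    return TrainedRun(model=model, history=history, best_epoch=meta.get("best_epoch", -1),
                      best_val_dice=meta.get("best_val_dice") or float("nan"),
                      config=config)
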