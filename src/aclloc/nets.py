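"""Trainable networks and their losses, at desk-scale capacity.

Three builders cover the cascade: a 3D U-Net for footprint/ligament
segmentation, a 3D U-Net regressing a single sigmoid heatmap channel (group
normalization throughout), and the 2D route's slice selector plus
single-level keypoint detector.  ``train`` is a deterministic seeded
momentum-SGD loop over single samples.

Default capacity is deliberately small (depth 3, 8 base channels): the
original full-scale networks needed a GPU farm, which is out of scope; these
run on one CPU core in minutes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from aclloc.nn.losses import cross_entropy_grad, detector_loss_grad, dice_focal_loss_grad
from aclloc.nn.models import Detector, SliceNet, UNet3D
from aclloc.nn.optim import SGD
from aclloc.targets import HeatmapTarget

__all__ = [
    "NetConfig",
    "LossConfig",
    "TrainConfig",
    "TrainingDivergence",
    "build_seg_net",
    "build_heatmap_net",
    "build_slice_net",
    "build_detector",
    "dice_focal_loss",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetConfig:
    depth: int = 3
    base_channels: int = 8
    norm: str = "group"
    groups: int = 4
    input_shape: tuple = (48, 48, 16)
    n_outputs: int = 1
    # axes halved at each level; the slice-selection net keeps its slice axis
    downsampled_axes: tuple = (0, 1, 2)

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")
        if self.norm not in ("group", "batch"):
            raise ValueError("norm must be 'group' or 'batch'")
        d = 2 ** (self.depth - 1)
        shape = self.input_shape[-3:]
        for ax in self.downsampled_axes:
            if ax < len(shape) and shape[ax] % d:
                raise ValueError(f"input dims {self.input_shape} not divisible by {d}")


@dataclass(frozen=True)
class LossConfig:
    dice_weight: float = 1.0
    focal_weight: float = 1.0
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25

    def __post_init__(self):
        if self.dice_weight < 0 or self.focal_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if self.dice_weight + self.focal_weight <= 0:
            raise ValueError("dice_weight + focal_weight must be > 0")
        if not 0 < self.focal_alpha < 1:
            raise ValueError("focal_alpha must lie in (0, 1)")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be >= 0")


@dataclass
class TrainConfig:
    epochs: int = 25
    lr: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 0.0
    seed: int = 0
    shuffle: bool = True
    loss: LossConfig = field(default_factory=LossConfig)


class TrainingDivergence(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def _register(model, kind: str, config: NetConfig, seed: int):
    model.build_info = {"kind": kind, "config": asdict(config), "seed": seed}
    return model


def build_seg_net(config: NetConfig, seed: int = 0) -> UNet3D:
    """3D U-Net producing per-voxel class scores (softmax over label channels)."""
    return _register(
        UNet3D(
            depth=config.depth,
            base_channels=config.base_channels,
            n_outputs=config.n_outputs,
            norm=config.norm,
            groups=config.groups,
            final_activation="softmax",
            seed=seed,
        ),
        "seg",
        config,
        seed,
    )


def build_heatmap_net(config: NetConfig, seed: int = 0) -> UNet3D:
    """3D U-Net with one sigmoid output channel (probability heatmap)."""
    return _register(
        UNet3D(
            depth=config.depth,
            base_channels=config.base_channels,
            n_outputs=1,
            norm=config.norm,
            groups=config.groups,
            final_activation="sigmoid",
            seed=seed,
        ),
        "heatmap",
        config,
        seed,
    )


def build_slice_net(config: NetConfig, seed: int = 0) -> SliceNet:
    """Slice-selection network; ``config.input_shape`` is (n_slices, H, W) with H = W = 256."""
    n_slices, h, w = config.input_shape
    if h != w:
        raise ValueError("slice net needs square in-plane input")
    return _register(
        SliceNet(
            n_slices=n_slices,
            in_plane=h,
            base_channels=config.base_channels,
            norm=config.norm,
            groups=config.groups,
            seed=seed,
        ),
        "slice",
        config,
        seed,
    )


def build_detector(config: NetConfig, seed: int = 0) -> Detector:
    """Single-level box-center keypoint detector for 2D inputs."""
    return _register(
        Detector(base_channels=config.base_channels, norm=config.norm, groups=config.groups, seed=seed),
        "detector",
        config,
        seed,
    )


def dice_focal_loss(pred, target, config: LossConfig = LossConfig()) -> float:
    """Scalar Dice + focal loss; ``target`` is a HeatmapTarget or a one-hot array.

    Invalid voxels of a HeatmapTarget contribute exactly nothing.
    """
    loss, _ = _loss_and_grad(pred, target, config)
    return loss


def _loss_and_grad(pred, target, config: LossConfig):
    pred = np.asarray(pred)
    if isinstance(target, HeatmapTarget):
        values = target.values
        invalid = target.invalid_mask
        if pred.ndim == values.ndim + 1:
            values = values[None]
        loss, grad = dice_focal_loss_grad(
            pred,
            values,
            invalid,
            dice_weight=config.dice_weight,
            focal_weight=config.focal_weight,
            focal_gamma=config.focal_gamma,
            focal_alpha=config.focal_alpha,
        )
    else:
        loss, grad = dice_focal_loss_grad(
            pred,
            np.asarray(target),
            None,
            dice_weight=config.dice_weight,
            focal_weight=config.focal_weight,
            focal_gamma=config.focal_gamma,
            focal_alpha=config.focal_alpha,
        )
    return loss, grad


def _step_loss(model, x, target, loss_config: LossConfig):
    """One forward pass + loss + gradient w.r.t. the model output."""
    kind = getattr(model, "build_info", {}).get("kind")
    pred = model.forward(x)
    if kind in ("seg", "heatmap", None):
        return _loss_and_grad(pred, target, loss_config)
    if kind == "slice":
        return cross_entropy_grad(pred, target)
    if kind == "detector":
        return detector_loss_grad(pred, target, stride=model.STRIDE)
    raise ValueError(f"unknown model kind {kind!r}")


def train(model, dataset, config: TrainConfig):
    """Train in place; returns ``(model, history)`` with per-epoch mean losses.

    Deterministic for a fixed seed under single-threaded execution.  Raises
    :class:`TrainingDivergence` on a non-finite loss.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    rng = np.random.default_rng(config.seed)
    opt = SGD(
        model.params(), lr=config.lr, momentum=config.momentum, weight_decay=config.weight_decay
    )
    history = []
    order = np.arange(len(dataset))
    for epoch in range(config.epochs):
        if config.shuffle:
            rng.shuffle(order)
        losses = []
        for i in order:
            x, target = dataset[i]
            loss, grad = _step_loss(model, x, target, config.loss)
            if not np.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite loss at epoch {epoch}, sample {int(i)}: {loss}"
                )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints: a single .npz holding the build info and all parameters.
# ---------------------------------------------------------------------------

_BUILDERS = {
    "seg": build_seg_net,
    "heatmap": build_heatmap_net,
    "slice": build_slice_net,
    "detector": build_detector,
}


def save_checkpoint(model, path) -> None:
    info = getattr(model, "build_info", None)
    if info is None:
        raise ValueError("model was not created by a builder; cannot checkpoint")
    arrays = {f"p{i}": p.value for i, p in enumerate(model.params())}
    np.savez(Path(path), meta=np.array(json.dumps(info)), **arrays)


def load_checkpoint(path):
    with np.load(Path(path), allow_pickle=False) as data:
        info = json.loads(str(data["meta"]))
        cfg = info["config"]
        cfg["input_shape"] = tuple(cfg["input_shape"])
        model = _BUILDERS[info["kind"]](NetConfig(**cfg), seed=info["seed"])
        params = model.params()
        for i, p in enumerate(params):
            p.value[...] = data[f"p{i}"]
    return model
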