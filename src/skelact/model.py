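"""Two-pathway (SlowFast-style) 3D CNN over heatmap volumes.

The slow pathway sees every ``slow_stride``-th frame at full channel
width and captures spatial detail; the fast pathway sees every frame at a
fraction of the width and captures temporal detail.  Time-strided lateral
convolutions fuse fast features into the slow pathway before each
residual stage.  Global spatiotemporal average pooling of both pathways
feeds a concatenated linear softmax head.

Defaults are deliberately tiny (slow_stride 4, fast width 1/8, two
residual stages of depth 1, 8 base channels) so the full viewpoint
experiment trains in minutes on one CPU core; every knob scales upward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .nn import (
    SGD,
    BatchNorm3d,
    Conv3d,
    GlobalAvgPool,
    Linear,
    ReLU,
    ResBlock3d,
    Sequential,
    cross_entropy_grad,
    softmax,
)
from .skeleton import ValidationError


class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    num_classes: int = 16
    slow_stride: int = 4
    fast_channel_fraction: float = 0.125
    base_channels: int = 8
    stage_depths: list[int] = [1, 1]
    lateral_connections: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ModelConfig":
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.slow_stride < 1:
            raise ValueError("slow_stride must be >= 1")
        if not 0 < self.fast_channel_fraction <= 1:
            raise ValueError("fast_channel_fraction must be in (0, 1]")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if not self.stage_depths or min(self.stage_depths) < 1:
            raise ValueError("stage_depths must be non-empty, all >= 1")
        return self


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    learning_rate: float = 0.05
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 240
    max_updates: int | None = None  # optional equal-compute budget
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TrainConfig":
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("invalid training hyperparameters")
        if self.max_updates is not None and self.max_updates < 1:
            raise ValueError("max_updates must be >= 1 when set")
        return self


@dataclass
class ClassifierOutput:
    """Softmax class probabilities and the argmax label (lowest index wins
    ties)."""

    class_probabilities: np.ndarray
    predicted_label: int


class SlowFastNet:
    """See module docstring.  Input volumes are (N, 1, T, H, W); T must be
    divisible by ``slow_stride``."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        cb = config.base_channels
        cf = max(1, round(cb * config.fast_channel_fraction))
        alpha = config.slow_stride
        self.fast_stem = Sequential(
            Conv3d(1, cf, (3, 3, 3), (1, 2, 2), bias=False, rng=rng),
            BatchNorm3d(cf), ReLU(),
        )
        self.slow_stem = Sequential(
            Conv3d(1, cb, (1, 3, 3), (1, 2, 2), bias=False, rng=rng),
            BatchNorm3d(cb), ReLU(),
        )
        self.stages_slow: list[Sequential] = []
        self.stages_fast: list[Sequential] = []
        self.laterals: list[Conv3d | None] = []
        slow_ch, fast_ch = cb, cf
        for i, depth in enumerate(config.stage_depths):
            if config.lateral_connections:
                self.laterals.append(
                    Conv3d(fast_ch, 2 * fast_ch, (alpha, 1, 1),
                           (alpha, 1, 1), pad="valid", bias=False, rng=rng)
                )
                slow_in = slow_ch + 2 * fast_ch
            else:
                self.laterals.append(None)
                slow_in = slow_ch
            stride = (1, 1, 1) if i == 0 else (1, 2, 2)
            slow_out = cb * (2 ** i)
            fast_out = cf * (2 ** i)
            sblocks = [ResBlock3d(slow_in, slow_out, (1, 3, 3), stride, rng=rng)]
            fblocks = [ResBlock3d(fast_ch, fast_out, (3, 3, 3), stride, rng=rng)]
            for _ in range(depth - 1):
                sblocks.append(ResBlock3d(slow_out, slow_out, (1, 3, 3), rng=rng))
                fblocks.append(ResBlock3d(fast_out, fast_out, (3, 3, 3), rng=rng))
            self.stages_slow.append(Sequential(*sblocks))
            self.stages_fast.append(Sequential(*fblocks))
            slow_ch, fast_ch = slow_out, fast_out
        self.pool_slow = GlobalAvgPool()
        self.pool_fast = GlobalAvgPool()
        self._slow_feat, self._fast_feat = slow_ch, fast_ch
        self.head = Linear(slow_ch + fast_ch, config.num_classes, rng=rng)

    # -- plumbing -----------------------------------------------------------
    def params(self):
        out = self.fast_stem.params() + self.slow_stem.params()
        for lat in self.laterals:
            if lat is not None:
                out += lat.params()
        for s in self.stages_slow + self.stages_fast:
            out += s.params()
        return out + self.head.params()

    def num_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, np.float32)
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValidationError(
                f"expected (N, 1, T, H, W) volumes, got {x.shape}"
            )
        alpha = self.config.slow_stride
        if x.shape[2] % alpha:
            raise ValidationError(
                f"T={x.shape[2]} not divisible by slow_stride={alpha}"
            )
        f = self.fast_stem.forward(x, train)
        s = self.slow_stem.forward(x[:, :, ::alpha], train)
        self._lat_ch = []
        for lat, sblock, fblock in zip(self.laterals, self.stages_slow,
                                       self.stages_fast):
            if lat is not None:
                lf = lat.forward(f, train)
                self._lat_ch.append(lf.shape[1])
                s = np.concatenate([s, lf], axis=1)
            else:
                self._lat_ch.append(0)
            s = sblock.forward(s, train)
            f = fblock.forward(f, train)
        ps = self.pool_slow.forward(s, train)
        pf = self.pool_fast.forward(f, train)
        feat = np.concatenate([ps, pf], axis=1)
        return self.head.forward(feat, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        ds = self.pool_slow.backward(dfeat[:, : self._slow_feat])
        df = self.pool_fast.backward(dfeat[:, self._slow_feat:])
        for lat, sblock, fblock, lch in zip(
            reversed(self.laterals), reversed(self.stages_slow),
            reversed(self.stages_fast), reversed(self._lat_ch),
        ):
            df = fblock.backward(df)
            dcat = sblock.backward(ds)
            if lat is not None:
                ds = dcat[:, : dcat.shape[1] - lch]
                df = df + lat.backward(dcat[:, dcat.shape[1] - lch:])
            else:
                ds = dcat
        self.fast_stem.backward(df)
        self.slow_stem.backward(ds)


def _as_batch(volumes) -> np.ndarray:
    """Accepts (N, T, H, W) arrays, lists of (T, H, W) arrays, or lists of
    HeatmapVolume; returns (N, 1, T, H, W)."""
    if isinstance(volumes, np.ndarray):
        arr = volumes
    else:
        arr = np.stack(
            [getattr(v, "values", v) for v in volumes]
        ) if len(volumes) else np.zeros((0, 1, 1, 1))
    if arr.ndim == 4:
        arr = arr[:, None]
    return np.asarray(arr, np.float32)


def build_model(config: ModelConfig) -> SlowFastNet:
    """Construct the two-pathway network; parameter initialization is
    reproducible from ``config.seed``."""
    return SlowFastNet(config)


def train(
    model: SlowFastNet,
    volumes,
    labels,
    train_config: TrainConfig,
) -> tuple[SlowFastNet, list[float]]:
    """SGD / cross-entropy training loop.

    Returns the model (trained in place) and the per-epoch mean loss
    history.  If ``max_updates`` is set, training stops after that many
    minibatch updates regardless of epochs — an equal-compute budget that
    keeps comparisons between differently sized training sets fair.
    """
    x = _as_batch(volumes)
    y = np.asarray(labels, int)
    if len(x) != len(y) or len(x) == 0:
        raise ValidationError("volumes and labels must align and be non-empty")
    present = np.unique(y)
    missing = set(range(model.config.num_classes)) - set(present.tolist())
    if missing:
        raise ValidationError(f"classes absent from training labels: {sorted(missing)}")
    rng = np.random.default_rng(train_config.seed)
    opt = SGD(model.params(), train_config.learning_rate,
              train_config.momentum, train_config.weight_decay)
    history: list[float] = []
    updates = 0
    for _ in range(train_config.max_epochs):
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            logits = model.forward(x[idx], train=True)
            loss, dlogits = cross_entropy_grad(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            updates += 1
            if (train_config.max_updates is not None
                    and updates >= train_config.max_updates):
                history.append(float(np.mean(losses)))
                return model, history
        history.append(float(np.mean(losses)))
    return model, history


def _all_layers(layer):
    from .nn import Layer, Sequential, ResBlock3d

    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _all_layers(sub)
    elif isinstance(layer, ResBlock3d):
        yield from _all_layers(layer.conv1)
        yield from _all_layers(layer.bn1)
        yield from _all_layers(layer.conv2)
        yield from _all_layers(layer.bn2)
        if layer.project:
            yield from _all_layers(layer.short_conv)
            yield from _all_layers(layer.short_bn)
    elif isinstance(layer, Layer):
        yield layer


def _state_arrays(model: SlowFastNet) -> list[np.ndarray]:
    """All learnable parameters plus batch-norm running statistics, in a
    deterministic order (used for checkpointing)."""
    modules = [model.fast_stem, model.slow_stem]
    modules += [lat for lat in model.laterals if lat is not None]
    modules += model.stages_slow + model.stages_fast + [model.head]
    arrays: list[np.ndarray] = []
    for module in modules:
        for layer in _all_layers(module):
            arrays += [p for p, _ in layer.params()]
            if isinstance(layer, BatchNorm3d):
                arrays += [layer.running_mean, layer.running_var]
    return arrays


def save_model(model: SlowFastNet, path) -> None:
    """Checkpoint the model config and all weights/statistics to .npz."""
    arrays = {f"arr_{i}": a for i, a in enumerate(_state_arrays(model))}
    np.savez(path, config=model.config.model_dump_json(), **arrays)


def load_model(path) -> SlowFastNet:
    with np.load(path, allow_pickle=False) as data:
        config = ModelConfig.model_validate_json(str(data["config"]))
        model = SlowFastNet(config)
        for i, target in enumerate(_state_arrays(model)):
            target[...] = data[f"arr_{i}"]
    return model


def predict(model: SlowFastNet, volumes, batch_size: int = 64
            ) -> list[ClassifierOutput]:
    """Deterministic inference; one output per volume."""
    x = _as_batch(volumes)
    if len(x) == 0:
        return []
    out: list[ClassifierOutput] = []
    for start in range(0, len(x), batch_size):
        probs = softmax(model.forward(x[start:start + batch_size], train=False))
        for p in probs:
            out.append(ClassifierOutput(p, int(np.argmax(p))))
    return out
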