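"""DeepLab-style segmentation network at desk scale.

Architecture: a small pre-activation residual encoder with atrous
(dilated) convolutions, followed by atrous spatial pyramid pooling (ASPP)
and a 1×1 classifier, with bilinear upsampling of the logits back to
input resolution. The ingredients mirror the full-scale design — residual
learning blocks ``x_{l+1} = x_l + f(x_l, w_l)``, dilated 3×3 kernels that
enlarge the receptive field at constant parameter count, and parallel
ASPP branches probing multiple sampling rates plus a global-pooling
branch — but the default "tiny" profile (2 stages × 2 blocks, 16 base
channels) is sized to train on a CPU in minutes. A "full-scale" profile
records the conventional ResNet-101/ASPP(6,12,18) configuration for
completeness; it is not exercised by the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (AvgPool2d, BatchNorm2d, BilinearUpsample, Conv2d, Layer,
                     Param, ReLU, Sequential, softmax)


@dataclass(frozen=True)
class NetConfig:
    n_stages: int = 2
    blocks_per_stage: tuple[int, ...] | int = 2
    base_channels: int = 16
    atrous_rates: tuple[int, ...] = (2, 4, 8)
    n_classes: int = 2
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self):
        if not self.atrous_rates or any(r < 1 for r in self.atrous_rates):
            raise ValueError("atrous_rates must be non-empty with all rates >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if isinstance(self.blocks_per_stage, int):
            object.__setattr__(self, "blocks_per_stage",
                               (self.blocks_per_stage,) * self.n_stages)
        if len(self.blocks_per_stage) != self.n_stages:
            raise ValueError("blocks_per_stage must have n_stages entries")
        if self.input_size[0] % 2 or self.input_size[1] % 2:
            raise ValueError("input_size dims must be even (one 2x downsample)")


TINY_PROFILE = NetConfig()
FULL_SCALE_PROFILE = NetConfig(
    n_stages=4, blocks_per_stage=(3, 4, 23, 3), base_channels=64,
    atrous_rates=(6, 12, 18), n_classes=2, input_size=(512, 512),
)
PROFILES = {"tiny": TINY_PROFILE, "full-scale": FULL_SCALE_PROFILE}


class ResidualBlock(Layer):
    """Pre-activation residual block: out = x + f(x); f = BN-ReLU-conv ×2.

    Zeroing both convolutions' weights and biases makes the block the
    exact identity on its input.
    """

    def __init__(self, channels: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        self.branch = Sequential(
            BatchNorm2d(channels), ReLU(),
            Conv2d(channels, channels, 3, dilation=dilation, rng=rng),
            BatchNorm2d(channels), ReLU(),
            Conv2d(channels, channels, 3, dilation=dilation, rng=rng),
        )

    def params(self):
        return self.branch.params()

    def children(self):
        return self.branch.layers

    def zero_branch(self):
        for conv in (self.branch.layers[2], self.branch.layers[5]):
            conv.w.value[:] = 0.0
            conv.b.value[:] = 0.0

    def forward(self, x, training):
        return x + self.branch.forward(x, training)

    def backward(self, gy):
        return gy + self.branch.backward(gy)


class ASPP(Layer):
    """Atrous spatial pyramid pooling: one dilated 3×3 branch per rate plus
    a global-average-pooling branch, concatenated and fused by 1×1 conv."""

    def __init__(self, cin: int, branch_channels: int, cout: int,
                 rates: tuple[int, ...], rng: np.random.Generator | None = None):
        if not rates:
            raise ValueError("ASPP needs at least one atrous rate")
        self.rates = tuple(rates)
        self.branches = [
            Sequential(Conv2d(cin, branch_channels, 3, dilation=r, rng=rng),
                       BatchNorm2d(branch_channels), ReLU())
            for r in self.rates
        ]
        self.pool_conv = Conv2d(cin, branch_channels, 1, rng=rng)
        self.pool_relu = ReLU()
        n_branches = len(self.rates) + 1
        self.project = Sequential(
            Conv2d(n_branches * branch_channels, cout, 1, rng=rng),
            BatchNorm2d(cout), ReLU(),
        )
        self.branch_channels = branch_channels

    def params(self):
        out = [p for br in self.branches for p in br.params()]
        out += self.pool_conv.params() + self.project.params()
        return out

    def children(self):
        return ([layer for br in self.branches for layer in br.layers]
                + [self.pool_conv, self.pool_relu] + self.project.layers)

    def forward(self, x, training):
        h, w = x.shape[2], x.shape[3]
        outs = [br.forward(x, training) for br in self.branches]
        pooled = x.mean(axis=(2, 3), keepdims=True)
        pooled = self.pool_relu.forward(
            self.pool_conv.forward(pooled, training), training)
        outs.append(np.broadcast_to(pooled, pooled.shape[:2] + (h, w)).copy())
        self._in_hw = (h, w)
        cat = np.concatenate(outs, axis=1)
        return self.project.forward(cat, training)

    def backward(self, gy):
        gcat = self.project.backward(gy)
        bc = self.branch_channels
        h, w = self._in_hw
        gx = None
        for i, br in enumerate(self.branches):
            g = br.backward(gcat[:, i * bc : (i + 1) * bc])
            gx = g if gx is None else gx + g
        gpool = gcat[:, len(self.branches) * bc :].sum(axis=(2, 3), keepdims=True)
        gpool = self.pool_conv.backward(self.pool_relu.backward(gpool))
        gx += gpool / (h * w)  # mean-pool spreads gradient uniformly
        return gx


class SegNet(Layer):
    """Encoder + ASPP + classifier producing per-pixel class logits."""

    def __init__(self, config: NetConfig = TINY_PROFILE, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        base = config.base_channels
        body: list[Layer] = [
            Conv2d(1, base, 3, rng=rng), BatchNorm2d(base), ReLU(),
            AvgPool2d(),
        ]
        ch = base
        for s in range(config.n_stages):
            ch_s = base * (2**s)
            dil = 2**s  # deeper stages widen the view atrously, no downsampling
            if ch_s != ch:
                body += [Conv2d(ch, ch_s, 1, rng=rng), BatchNorm2d(ch_s), ReLU()]
                ch = ch_s
            body += [ResidualBlock(ch, dilation=dil, rng=rng)
                     for _ in range(config.blocks_per_stage[s])]
        self.body = Sequential(*body)
        self.aspp = ASPP(ch, base, ch, config.atrous_rates, rng=rng)
        self.classifier = Conv2d(ch, config.n_classes, 1, rng=rng)
        self.upsample = BilinearUpsample(config.input_size)

    def params(self):
        return (self.body.params() + self.aspp.params()
                + self.classifier.params())

    def children(self):
        return self.body.layers + [self.aspp, self.classifier, self.upsample]

    def forward(self, x, training=False):
        z = self.body.forward(x.astype(np.float32), training)
        z = self.aspp.forward(z, training)
        z = self.classifier.forward(z, training)
        return self.upsample.forward(z, training)

    def backward(self, gy):
        gy = self.upsample.backward(gy)
        gy = self.classifier.backward(gy)
        gy = self.aspp.backward(gy)
        return self.body.backward(gy)

    # --- serialization -------------------------------------------------
    def _batchnorms(self):
        out = []

        def walk(layer):
            if isinstance(layer, BatchNorm2d):
                out.append(layer)
            for child in getattr(layer, "children", list)() or []:
                walk(child)
            if isinstance(layer, Sequential):
                for child in layer.layers:
                    walk(child)

        walk(self.body)
        walk(self.aspp)
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.value for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"bn{i}_mean"] = bn.running_mean
            state[f"bn{i}_var"] = bn.running_var
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = state[f"p{i}"].astype(np.float32)
            p.grad = np.zeros_like(p.value)
            p.velocity = np.zeros_like(p.value)
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean = state[f"bn{i}_mean"].astype(np.float32)
            bn.running_var = state[f"bn{i}_var"].astype(np.float32)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel softmax probabilities, (H, W, n_classes)."""
        h, w = self.config.input_size
        if image.shape != (h, w):
            raise ValueError(
                f"image shape {image.shape} does not match the network input "
                f"size {(h, w)}")
        x = image[None, None].astype(np.float32)
        logits = self.forward(x, training=False)
        return np.moveaxis(softmax(logits, axis=1)[0], 0, -1).astype(np.float64)
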