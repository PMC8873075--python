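"""3D U-Net architecture shared by all three cascade steps, plus prediction.

The contracting path has, under the default configuration (4 levels, two
convolutions per level, one bottleneck convolution), nine 3x3x3 convolutional
layers, each followed by batch normalization and ReLU, with max pooling and
dropout between levels.  The expansive path alternates 2x2x2 transposed
convolutions (with skip concatenation) and convolution blocks; the head is a
1x1x1 convolution with sigmoid activation producing a voxel-wise foreground
probability.  The first convolution has 18 filters by default; filter counts
double per level.

Desk-scale tests shrink ``base_filters`` and ``levels``; the architecture is
fully convolutional, so any input whose spatial dimensions are divisible by
``2**levels`` can be processed (others are edge-padded at predict time and
cropped back).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from ._nn import Adam, BatchNorm, Conv3d, ConvTranspose2, Dropout, MaxPool2, ReLU

__all__ = [
    "NetworkSpec",
    "UNet3D",
    "TrainedModel",
    "build_unet",
    "predict_probabilities",
    "ensemble_predict",
    "save_model",
    "load_model",
]


@dataclass
class NetworkSpec:
    """Structural hyperparameters of the U-Net.

    ``contracting_conv_count`` is ``levels * convs_per_level + 1`` (the +1 is
    the single bottleneck convolution); the default configuration therefore
    has nine convolutional layers on the contracting path.
    """

    base_filters: int = 18
    levels: int = 4
    convs_per_level: int = 2
    dropout_rate: float = 0.2
    in_channels: int = 1

    def __post_init__(self):
        if self.base_filters < 1 or self.levels < 1 or self.convs_per_level < 1:
            raise ValueError("base_filters, levels and convs_per_level must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def contracting_conv_count(self) -> int:
        return self.levels * self.convs_per_level + 1

    @property
    def pool_factor(self) -> int:
        return 2 ** self.levels


class UNet3D:
    """The wired network: layer objects plus forward/backward execution."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = [spec.base_filters * 2**l for l in range(spec.levels + 1)]
        self.down_blocks = []  # per level: list of (conv, bn, relu)
        self.pools = []
        self.dropouts = []
        c = spec.in_channels
        for l in range(spec.levels):
            block = []
            for _ in range(spec.convs_per_level):
                block.append((Conv3d(c, f[l], 3, rng), BatchNorm(f[l]), ReLU()))
                c = f[l]
            self.down_blocks.append(block)
            self.pools.append(MaxPool2())
            self.dropouts.append(Dropout(spec.dropout_rate))
        self.bottleneck = (Conv3d(c, f[spec.levels], 3, rng), BatchNorm(f[spec.levels]), ReLU())
        c = f[spec.levels]
        self.up_convs = []
        self.up_blocks = []
        for l in reversed(range(spec.levels)):
            self.up_convs.append(ConvTranspose2(c, f[l], rng))
            block = []
            c = 2 * f[l]
            for _ in range(spec.convs_per_level):
                block.append((Conv3d(c, f[l], 3, rng), BatchNorm(f[l]), ReLU()))
                c = f[l]
            self.up_blocks.append(block)
        self.head = Conv3d(c, 1, 1, rng)

    # -- layer bookkeeping -------------------------------------------------
    def layers(self):
        out = []
        for block, pool, drop in zip(self.down_blocks, self.pools, self.dropouts):
            for conv, bn, relu in block:
                out += [conv, bn, relu]
            out += [pool, drop]
        out += list(self.bottleneck)
        for up, block in zip(self.up_convs, self.up_blocks):
            out.append(up)
            for conv, bn, relu in block:
                out += [conv, bn, relu]
        out.append(self.head)
        return out

    # -- execution ---------------------------------------------------------
    @staticmethod
    def _run_block(block, x, train, rng):
        for conv, bn, relu in block:
            x = relu.forward(bn.forward(conv.forward(x, train, rng), train, rng), train, rng)
        return x

    @staticmethod
    def _back_block(block, g):
        for conv, bn, relu in reversed(block):
            g = conv.backward(bn.backward(relu.backward(g)))
        return g

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """x: (N, D, H, W, C) float32, dims divisible by 2**levels. Returns probabilities."""
        skips = []
        for block, pool, drop in zip(self.down_blocks, self.pools, self.dropouts):
            x = self._run_block(block, x, train, rng)
            skips.append(x)
            x = drop.forward(pool.forward(x, train, rng), train, rng)
        x = self._run_block([self.bottleneck], x, train, rng)
        self._concat_sizes = []
        for up, block, skip in zip(self.up_convs, self.up_blocks, reversed(skips)):
            x = up.forward(x, train, rng)
            self._concat_sizes.append((skip.shape[-1], x.shape[-1]))
            x = np.concatenate([skip, x], axis=-1)
            x = self._run_block(block, x, train, rng)
        z = self.head.forward(x, train, rng)
        prob = 1.0 / (1.0 + np.exp(-z))
        if train:
            self._prob = prob
        return prob

    def backward(self, gprob: np.ndarray) -> None:
        """Backpropagate dL/dprob through the whole network (after a train-mode forward)."""
        p = self._prob
        self._prob = None
        g = (gprob * p * (1.0 - p)).astype(np.float32)
        g = self.head.backward(g)
        skip_grads = []
        for i in reversed(range(len(self.up_blocks))):
            g = self._back_block(self.up_blocks[i], g)
            cs, _ = self._concat_sizes[i]
            gskip, g = g[..., :cs], g[..., cs:]
            skip_grads.append(gskip)
            g = self.up_convs[i].backward(np.ascontiguousarray(g))
        g = self._back_block([self.bottleneck], g)
        skip_grads.reverse()  # now indexed by level (deepest first)
        for l in reversed(range(len(self.down_blocks))):
            g = self.pools[l].backward(self.dropouts[l].backward(g))
            g = g + skip_grads[len(self.down_blocks) - 1 - l]
            g = self._back_block(self.down_blocks[l], g)

    # -- weight (de)serialization -------------------------------------------
    def state_arrays(self):
        arrs = {}
        for i, layer in enumerate(self.layers()):
            for j, (p, _) in enumerate(layer.parameters()):
                arrs[f"p_{i}_{j}"] = p
            if isinstance(layer, BatchNorm):
                arrs[f"rm_{i}"] = layer.running_mean
                arrs[f"rv_{i}"] = layer.running_var
        return arrs

    def load_state_arrays(self, arrs):
        for i, layer in enumerate(self.layers()):
            for j, (p, _) in enumerate(layer.parameters()):
                p[...] = arrs[f"p_{i}_{j}"]
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = arrs[f"rm_{i}"]
                layer.running_var[...] = arrs[f"rv_{i}"]


@dataclass
class TrainedModel:
    """A network together with its spec and training provenance."""

    spec: NetworkSpec
    net: UNet3D
    training_meta: dict = field(default_factory=dict)

    def predict(self, values: np.ndarray) -> np.ndarray:
        return _predict_array(self.net, values)


def build_unet(spec: NetworkSpec | None = None, seed: int = 0) -> TrainedModel:
    """Construct an (untrained) U-Net model from a structural spec."""
    spec = spec or NetworkSpec()
    return TrainedModel(spec=spec, net=UNet3D(spec, seed=seed), training_meta={"seed": seed})


def _pad_to_multiple(values: np.ndarray, m: int):
    shape = np.asarray(values.shape)
    target = (np.ceil(shape / m) * m).astype(int)
    pads = [(0, int(t - s)) for s, t in zip(shape, target)]
    return np.pad(values, pads, mode="edge"), values.shape


def _predict_array(net: UNet3D, values: np.ndarray) -> np.ndarray:
    """Run inference on a raw 3D array (normalized intensities); pads to a
    pooling-compatible shape and crops back."""
    padded, orig_shape = _pad_to_multiple(values.astype(np.float32), net.spec.pool_factor)
    x = padded[None, ..., None]
    prob = net.forward(x, train=False)[0, ..., 0]
    return prob[: orig_shape[0], : orig_shape[1], : orig_shape[2]]


def predict_probabilities(model: TrainedModel, vol) -> "object":
    """Voxel-wise foreground probabilities on the grid of ``vol``.

    ``vol`` is a :class:`aorticroot.volume_io.Volume` whose intensities are
    expected to be normalized; the returned probability map shares its grid
    metadata.
    """
    prob = model.predict(vol.values)
    return vol.with_values(prob)


def ensemble_predict(models: Sequence[TrainedModel], vol) -> "object":
    """Voxel-wise arithmetic mean of the member probability maps."""
    models = list(models)
    if not models:
        raise ValueError("ensemble_predict requires at least one model")
    acc = None
    for m in models:
        p = m.predict(vol.values)
        acc = p if acc is None else acc + p
    return vol.with_values(acc / len(models))


def save_model(model: TrainedModel, path) -> None:
    """Save spec + weights + training metadata as a single .npz-based file."""
    arrs = model.net.state_arrays()
    meta = {"spec": asdict(model.spec), "training_meta": model.training_meta}
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrs)


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec = NetworkSpec(**meta["spec"])
        net = UNet3D(spec, seed=0)
        net.load_state_arrays(data)
    return TrainedModel(spec=spec, net=net, training_meta=meta["training_meta"])
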