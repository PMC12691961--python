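"""Network architectures: sex classifier and sex-conditioned segmenter.

Both networks share the same encoder design: per resolution level, two
same-padded 3x3 (3x3x3 in 3D) convolutions with ReLU, channels doubling
per level, 2x max-pooling between levels.

* The **segmenter** is a symmetric encoder–decoder (U-Net): stride-2
  transposed convolutions upsample, skip connections concatenate encoder
  features at matching resolution, and a final 1x1 convolution produces a
  single logit map; a sigmoid turns it into a per-voxel probability.
  Its input is the image channel plus ``sex_channels`` constant one-hot
  planes carrying the (true or predicted) patient sex.
* The **classifier** is the same encoder followed by global average
  pooling and a linear head producing a single logit, sigmoid-mapped to
  the probability that the patient is male.

The two stages are architecturally shared but trained independently with
separate weights.  Networks are constructible at ``dims=2`` (axial
slices) and ``dims=3`` through the same code path.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .layers import Conv, ConvTranspose, GlobalAvgPool, Layer, Linear, MaxPool, ReLU

__all__ = [
    "NetConfig",
    "SexLabel",
    "build_classifier",
    "build_segmenter",
    "condition_input",
    "sigmoid",
    "bce_with_logits",
    "Adam",
    "save_checkpoint",
    "load_checkpoint",
]

SEXES = ("male", "female")


@dataclass
class NetConfig:
    """Architecture hyperparameters shared by classifier and segmenter."""

    n_levels: int = 4
    base_channels: int = 16
    conv_kernel: int = 3
    dims: int = 3
    sex_channels: int = 2

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")

    @property
    def divisor(self) -> int:
        """Input extents must be divisible by this (2^(n_levels-1))."""
        return 2 ** (self.n_levels - 1)


@dataclass
class SexLabel:
    """Patient sex with its one-hot channel encoding (male, female)."""

    value: str

    def __post_init__(self) -> None:
        if self.value not in SEXES:
            raise ValueError(f"unknown sex: {self.value!r}")

    @property
    def onehot(self) -> np.ndarray:
        return np.asarray(
            [1.0, 0.0] if self.value == "male" else [0.0, 1.0], dtype=np.float32
        )


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - y) / z.size
    return float(loss.mean()), grad.astype(np.float32)


def _layer_rngs(seed: int, n: int = 64):
    """Independent per-layer init streams.

    Spawned children keep layer initializations independent of each
    other's tensor sizes, so two architectures sharing a layout (e.g. the
    conditioned and unconditioned segmenter) share their initial weights
    wherever their shapes agree.
    """
    return iter([np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)])


class ConvBlock:
    """Two conv+ReLU pairs at one resolution level."""

    def __init__(self, c_in, c_out, ndim, ksize, rngs):
        self.layers = [
            Conv(c_in, c_out, ndim, ksize, next(rngs)), ReLU(),
            Conv(c_out, c_out, ndim, ksize, next(rngs)), ReLU(),
        ]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy


class Network:
    """Base: parameter iteration, counting, deterministic eval forward."""

    config: NetConfig
    kind: str

    def _all_layers(self) -> list[Layer]:  # pragma: no cover
        raise NotImplementedError

    def parameters(self):
        for layer in self._all_layers():
            for key in layer.params:
                yield layer, key

    def n_params(self) -> int:
        return sum(layer.params[key].size for layer, key in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[key].copy() for layer, key in self.parameters()]

    def set_weights(self, weights) -> None:
        for (layer, key), w in zip(self.parameters(), weights):
            layer.params[key] = w.copy()

    def _check_input(self, x: np.ndarray, c_in: int) -> None:
        if x.ndim != self.config.dims + 2:
            raise ValueError(
                f"expected (N, C, {'x'.join(['S'] * self.config.dims)}) input, "
                f"got {x.ndim}D array"
            )
        if x.shape[1] != c_in:
            raise ValueError(f"channel count mismatch: got {x.shape[1]}, expected {c_in}")
        div = self.config.divisor
        if any(s % div for s in x.shape[2:]):
            raise ValueError(
                f"spatial extents {x.shape[2:]} not divisible by {div} "
                f"(required for {self.config.n_levels} levels)"
            )


class Segmenter(Network):
    """Sex-conditioned U-Net; forward maps (1 + sex_channels)-channel input
    to per-voxel logits of the same spatial shape."""

    kind = "segmenter"

    def __init__(self, config: NetConfig, rngs):
        self.config = config
        d, k = config.dims, config.conv_kernel
        self.c_in = 1 + config.sex_channels
        chans = [config.base_channels * 2 ** i for i in range(config.n_levels)]
        self.enc = []
        c_prev = self.c_in
        for level, c in enumerate(chans[:-1]):
            block = ConvBlock(1 if level == 0 else c_prev, c, d, k, rngs)
            if level == 0 and config.sex_channels > 0:
                # Zero-init the conditioning pathway: the image-channel
                # weights are drawn exactly as in an unconditioned network,
                # the sex-plane weights start at zero and grow only where
                # the prior reduces the loss.  Random weights on constant
                # channels would inject per-filter bias noise that markedly
                # slows early training; zero-init also makes conditioned
                # and unconditioned networks start functionally identical.
                conv0 = block.layers[0]
                w = np.zeros((c, self.c_in) + (k,) * d, dtype=np.float32)
                w[:, :1] = conv0.params["w"]
                conv0.params["w"] = w
                conv0.c_in = self.c_in
            self.enc.append(block)
            c_prev = c
        self.pools = [MaxPool() for _ in chans[:-1]]
        self.bottleneck = ConvBlock(c_prev, chans[-1], d, k, rngs)
        self.ups, self.dec = [], []
        c_prev = chans[-1]
        for c_skip in reversed(chans[:-1]):
            self.ups.append(ConvTranspose(c_prev, c_skip, d, next(rngs)))
            self.dec.append(ConvBlock(2 * c_skip, c_skip, d, k, rngs))
            c_prev = c_skip
        self.head = Conv(chans[0], 1, d, ksize=1, rng=next(rngs))

    def _all_layers(self):
        out = []
        for block in self.enc:
            out += block.layers
        out += self.bottleneck.layers
        for up, block in zip(self.ups, self.dec):
            out.append(up)
            out += block.layers
        out.append(self.head)
        return out

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_input(x, self.c_in)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-voxel probability map in (0, 1)."""
        return sigmoid(self.forward_logits(x, train))

    def backward(self, gy: np.ndarray) -> None:
        gy = self.head.backward(gy)
        skip_grads = []
        for up, block, c_skip in zip(
            reversed(self.ups), reversed(self.dec), self._skip_channels[::-1]
        ):
            gy = block.backward(gy)
            skip_grads.append(gy[:, :c_skip])
            gy = up.backward(gy[:, c_skip:])
        gy = self.bottleneck.backward(gy)
        # walk back through encoder, adding skip gradients (deepest first)
        for block, pool, gskip in zip(
            reversed(self.enc), reversed(self.pools), skip_grads[::-1]
        ):
            gy = pool.backward(gy) + gskip
            gy = block.backward(gy)


class Classifier(Network):
    """Encoder + global average pooling + linear head -> P(male)."""

    kind = "classifier"

    def __init__(self, config: NetConfig, rngs):
        self.config = config
        d, k = config.dims, config.conv_kernel
        self.c_in = 1
        chans = [config.base_channels * 2 ** i for i in range(config.n_levels)]
        self.enc = []
        c_prev = self.c_in
        for c in chans[:-1]:
            self.enc.append(ConvBlock(c_prev, c, d, k, rngs))
            c_prev = c
        self.pools = [MaxPool() for _ in chans[:-1]]
        self.bottleneck = ConvBlock(c_prev, chans[-1], d, k, rngs)
        self.gap = GlobalAvgPool()
        self.headlin = Linear(chans[-1], 1, next(rngs))

    def _all_layers(self):
        out = []
        for block in self.enc:
            out += block.layers
        out += self.bottleneck.layers
        out.append(self.headlin)
        return out

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_input(x, self.c_in)
        for block, pool in zip(self.enc, self.pools):
            x = pool.forward(block.forward(x, train), train)
        x = self.bottleneck.forward(x, train)
        x = self.gap.forward(x, train)
        return self.headlin.forward(x, train)[:, 0]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Probability that each subject is male, shape (N,)."""
        return sigmoid(self.forward_logits(x, train))

    def backward(self, gy: np.ndarray) -> None:
        gy = self.headlin.backward(gy[:, None])
        gy = self.gap.backward(gy)
        gy = self.bottleneck.backward(gy)
        for block, pool in zip(reversed(self.enc), reversed(self.pools)):
            gy = block.backward(pool.backward(gy))


def build_classifier(config: NetConfig, seed: int = 0) -> Classifier:
    """Sex-classification network with seeded Kaiming-uniform init."""
    return Classifier(config, _layer_rngs(seed))


def build_segmenter(config: NetConfig, seed: int = 0) -> Segmenter:
    """Sex-conditioned encoder–decoder with seeded Kaiming-uniform init."""
    return Segmenter(config, _layer_rngs(seed))


def condition_input(image: np.ndarray, sex: SexLabel | str) -> np.ndarray:
    """Concatenate constant one-hot sex planes onto a normalized image.

    ``image`` is (*spatial,) or (1, *spatial); returns (1 + 2, *spatial):
    channel 0 the image, channel 1 the male plane, channel 2 the female
    plane (exactly one of them all-ones).
    """
    if isinstance(sex, str):
        sex = SexLabel(sex)
    img = np.asarray(image, dtype=np.float32)
    if img.ndim >= 2 and img.shape[0] == 1:
        img = img[0]
    planes = [np.full(img.shape, v, dtype=np.float32) for v in sex.onehot]
    return np.stack([img] + planes, axis=0)


class Adam:
    """Adam optimizer over a Network's parameters."""

    def __init__(self, net: Network, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[k]) for layer, k in net.parameters()]
        self.v = [np.zeros_like(layer.params[k]) for layer, k in net.parameters()]

    def step(self) -> None:
        self.t += 1
        for i, (layer, key) in enumerate(self.net.parameters()):
            g = layer.grads[key].astype(np.float32)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            layer.params[key] = (
                layer.params[key] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(np.float32)


def save_checkpoint(net: Network, path) -> None:
    """Self-describing checkpoint: config JSON + weight arrays."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"kind": net.kind, "config": asdict(net.config)}
    arrays = {f"w{i}": w for i, w in enumerate(net.get_weights())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> Network:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = NetConfig(**meta["config"])
        net = build_classifier(config) if meta["kind"] == "classifier" else build_segmenter(config)
        weights = [data[f"w{i}"] for i in range(len(list(net.parameters())))]
    net.set_weights(weights)
    return net
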