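"""The grouped-convolution CNN classifier, implemented in NumPy.

Architecture (input 19 x 45 x 100, channels x frequencies x time; no padding
anywhere):

====================  ==========  ======  ========  ==============
layer                 out chans   groups  kernel    output
====================  ==========  ======  ========  ==============
conv + ReLU           950         19      1 x 5     950 x 45 x 96
max-pool                          -       2 x 2     950 x 22 x 48
conv + ReLU           1900        50      5 x 5     1900 x 18 x 44
max-pool                          -       2 x 2     1900 x 9 x 22
conv + ReLU           150         1       3 x 3     150 x 7 x 20
max-pool (identity)               -       1 x 1     150 x 7 x 20
fully connected                   -       -         2 (no bias)
softmax                           -       -         2
====================  ==========  ======  ========  ==============

The first convolution is fully depthwise (one group per EEG channel), the
second grouped with 50 groups, the third ungrouped.  Convolutions carry
biases; the final linear layer does not.  Pooling kernels are written
``1 x 2 x 2`` in (channel, frequency, time) terms - there is never pooling
across channels.  Weights use Kaiming-uniform initialization.

Convolutions are evaluated as im2col + BLAS sgemm per group, with forward and
backward passes written out by hand, so the network trains without any
autograd framework.  Internally activations are kept channel-major
``(C, B, H, W)`` so that every group's slab is contiguous and convolution
outputs are written straight into place; everything is float32.

Numerical notes: the max-pool backward recomputes the winner mask by
comparing the cached input against the pooled output.  Blocks whose maximum
is tied can route gradient to several positions, but positive-value ties have
probability zero on continuous activations and zero-valued ties are
annihilated by the preceding ReLU's gradient mask, so training dynamics match
an argmax-routed implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError

__all__ = [
    "ArchSpec",
    "ConvSpec",
    "PoolSpec",
    "FCSpec",
    "CNNModel",
    "build_model",
    "layer_output_shapes",
    "count_parameters",
    "forward",
    "softmax",
    "save_checkpoint",
    "load_checkpoint",
]

INPUT_SHAPE = (19, 45, 100)


# ---------------------------------------------------------------------------
# architecture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvSpec:
    out_channels: int
    groups: int
    kernel: tuple[int, int]
    bias: bool = True


@dataclass(frozen=True)
class PoolSpec:
    kernel: tuple[int, int]  # (frequency, time); (1, 1) is the identity


@dataclass(frozen=True)
class FCSpec:
    out_features: int
    bias: bool = False


@dataclass(frozen=True)
class ArchSpec:
    """Layer sequence and input shape; the default is the canonical network."""

    input_shape: tuple[int, int, int] = INPUT_SHAPE
    layers: tuple = (
        ConvSpec(950, 19, (1, 5)),
        PoolSpec((2, 2)),
        ConvSpec(1900, 50, (5, 5)),
        PoolSpec((2, 2)),
        ConvSpec(150, 1, (3, 3)),
        PoolSpec((1, 1)),
        FCSpec(2, bias=False),
    )


def layer_output_shapes(spec: ArchSpec = ArchSpec()) -> list[tuple[int, ...]]:
    """Shape after each layer (valid convolution, floor-division pooling).

    For the fully connected layer two entries are produced: the flattened
    input size and the output size.
    """
    c, h, w = spec.input_shape
    shapes: list[tuple[int, ...]] = []
    for layer in spec.layers:
        if isinstance(layer, ConvSpec):
            if c % layer.groups or layer.out_channels % layer.groups:
                raise ConfigError(
                    f"channels {c}->{layer.out_channels} not divisible by {layer.groups} groups"
                )
            kh, kw = layer.kernel
            c, h, w = layer.out_channels, h - kh + 1, w - kw + 1
            if h <= 0 or w <= 0:
                raise ConfigError("convolution output dimension non-positive")
            shapes.append((c, h, w))
        elif isinstance(layer, PoolSpec):
            h, w = h // layer.kernel[0], w // layer.kernel[1]
            if h <= 0 or w <= 0:
                raise ConfigError("pooling output dimension non-positive")
            shapes.append((c, h, w))
        elif isinstance(layer, FCSpec):
            shapes.append((c * h * w,))
            shapes.append((layer.out_features,))
            c, h, w = layer.out_features, 1, 1
    return shapes


# ---------------------------------------------------------------------------
# layers (internal layout: channel-major (C, B, H, W), float32)
# ---------------------------------------------------------------------------

class _ConvReLU:
    """Valid grouped 2-D convolution over (frequency, time), fused with ReLU."""

    def __init__(self, in_channels: int, spec: ConvSpec):
        self.in_channels = in_channels
        self.out_channels = spec.out_channels
        self.groups = spec.groups
        self.kh, self.kw = spec.kernel
        self.cg = in_channels // spec.groups
        self.og = spec.out_channels // spec.groups
        self.W = np.zeros((self.out_channels, self.cg, self.kh, self.kw), np.float32)
        self.b = np.zeros(self.out_channels, np.float32) if spec.bias else None
        self.dW = self.db = None
        self._cache = None

    def init_params(self, rng: np.random.Generator) -> None:
        # Kaiming-uniform, leaky-relu slope sqrt(5): bound = 1 / sqrt(fan_in)
        fan_in = self.cg * self.kh * self.kw
        bound = 1.0 / np.sqrt(fan_in)
        self.W[:] = rng.uniform(-bound, bound, self.W.shape).astype(np.float32)
        if self.b is not None:
            self.b[:] = rng.uniform(-bound, bound, self.b.shape).astype(np.float32)

    def parameters(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def gradients(self):
        return [self.dW] if self.b is None else [self.dW, self.db]

    def _group_cols(self, x: np.ndarray, g: int) -> np.ndarray:
        """im2col for one group: (cg * kh * kw, B * Ho * Wo), contiguous."""
        xg = x[g * self.cg : (g + 1) * self.cg]
        sw = sliding_window_view(xg, (self.kh, self.kw), axis=(2, 3))
        b, ho, wo = sw.shape[1:4]
        return np.ascontiguousarray(sw.transpose(0, 4, 5, 1, 2, 3)).reshape(
            self.cg * self.kh * self.kw, b * ho * wo
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        _, b, h, w = x.shape
        ho, wo = h - self.kh + 1, w - self.kw + 1
        out = np.empty((self.out_channels, b, ho, wo), np.float32)
        wm = self.W.reshape(self.groups, self.og, -1)
        cols_cache = [] if train else None
        for g in range(self.groups):
            cols = self._group_cols(x, g)
            np.matmul(wm[g], cols, out=out[g * self.og : (g + 1) * self.og].reshape(self.og, -1))
            if train:
                cols_cache.append(cols)
        if self.b is not None:
            out += self.b[:, None, None, None]
        np.maximum(out, 0.0, out=out)  # fused ReLU
        if train:
            self._cache = (x.shape, cols_cache, out)
        return out

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        in_shape, cols_cache, out = self._cache
        _, b, ho, wo = dy.shape
        dy = np.where(out > 0, dy, np.float32(0.0))  # ReLU gradient
        wm = self.W.reshape(self.groups, self.og, -1)
        self.dW = np.empty_like(self.W)
        dwm = self.dW.reshape(self.groups, self.og, -1)
        if self.b is not None:
            self.db = dy.sum(axis=(1, 2, 3)).astype(np.float32)
        dx = np.zeros(in_shape, np.float32) if need_dx else None
        for g in range(self.groups):
            cols = cols_cache[g]
            dy_g = dy[g * self.og : (g + 1) * self.og].reshape(self.og, -1)
            np.matmul(dy_g, cols.T, out=dwm[g])
            if need_dx:
                dcols = (wm[g].T @ dy_g).reshape(self.cg, self.kh, self.kw, b, ho, wo)
                gslice = dx[g * self.cg : (g + 1) * self.cg]
                for i in range(self.kh):
                    for j in range(self.kw):
                        gslice[:, :, i : i + ho, j : j + wo] += dcols[:, i, j]
        self._cache = None
        return dx


class _MaxPool:
    """Non-overlapping (ph, pw) max pooling; trailing remainder is cropped."""

    def __init__(self, spec: PoolSpec):
        self.ph, self.pw = spec.kernel
        self._cache = None

    def init_params(self, rng):  # no parameters
        pass

    def parameters(self):
        return []

    def gradients(self):
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        ph, pw = self.ph, self.pw
        if ph == 1 and pw == 1:
            return x
        h, w = x.shape[2], x.shape[3]
        hp, wp = h // ph, w // pw
        a = x[:, :, : hp * ph, : wp * pw]
        out = a[:, :, 0::ph, 0::pw].copy()
        for i in range(ph):
            for j in range(pw):
                if i or j:
                    np.maximum(out, a[:, :, i::ph, j::pw], out=out)
        if train:
            self._cache = (x, out)
        return out

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray:
        if self.ph == 1 and self.pw == 1:
            return dy
        x, out = self._cache
        hp, wp = out.shape[2], out.shape[3]
        dx = np.zeros_like(x)
        for i in range(self.ph):
            for j in range(self.pw):
                sl = x[:, :, i : hp * self.ph : self.ph, j : wp * self.pw : self.pw]
                dx[:, :, i : hp * self.ph : self.ph, j : wp * self.pw : self.pw] = np.where(
                    sl == out, dy, np.float32(0.0)
                )
        self._cache = None
        return dx


class _Linear:
    def __init__(self, in_features: int, spec: FCSpec):
        self.in_features = in_features
        self.out_features = spec.out_features
        self.W = np.zeros((spec.out_features, in_features), np.float32)
        self.b = np.zeros(spec.out_features, np.float32) if spec.bias else None
        self.dW = self.db = None
        self._cache = None

    def init_params(self, rng: np.random.Generator) -> None:
        bound = 1.0 / np.sqrt(self.in_features)
        self.W[:] = rng.uniform(-bound, bound, self.W.shape).astype(np.float32)
        if self.b is not None:
            self.b[:] = rng.uniform(-bound, bound, self.b.shape).astype(np.float32)

    def parameters(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def gradients(self):
        return [self.dW] if self.b is None else [self.dW, self.db]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # (C, B, h, w) -> (B, C*h*w), feature order (channel, freq, time)
        c, b = x.shape[0], x.shape[1]
        flat = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(b, -1)
        out = flat @ self.W.T
        if self.b is not None:
            out += self.b[None, :]
        if train:
            self._cache = (flat, x.shape)
        return out

    def backward(self, dy: np.ndarray, need_dx: bool = True):
        flat, shape = self._cache
        self.dW = (dy.T @ flat).astype(np.float32)
        if self.b is not None:
            self.db = dy.sum(axis=0).astype(np.float32)
        self._cache = None
        if not need_dx:
            return None
        dflat = dy @ self.W  # (B, C*h*w)
        c, b, h, w = shape
        return np.ascontiguousarray(dflat.reshape(b, c, h, w).transpose(1, 0, 2, 3))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class CNNModel:
    """The instantiated network: an ordered layer list plus its spec and seed."""

    def __init__(self, spec: ArchSpec, seed: int):
        self.spec = spec
        self.seed = int(seed)
        self.output_shapes = layer_output_shapes(spec)  # validates the chain
        self.layers: list = []
        c, h, w = spec.input_shape
        for layer in spec.layers:
            if isinstance(layer, ConvSpec):
                self.layers.append(_ConvReLU(c, layer))
                kh, kw = layer.kernel
                c, h, w = layer.out_channels, h - kh + 1, w - kw + 1
            elif isinstance(layer, PoolSpec):
                self.layers.append(_MaxPool(layer))
                h, w = h // layer.kernel[0], w // layer.kernel[1]
            elif isinstance(layer, FCSpec):
                self.layers.append(_Linear(c * h * w, layer))
            else:
                raise ConfigError(f"unknown layer spec {layer!r}")
        rng = np.random.default_rng(self.seed)
        for layer in self.layers:
            layer.init_params(rng)

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Pre-softmax scores for a (B, C, H, W) batch (or one (C, H, W) tensor)."""
        x = np.asarray(x, np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.spec.input_shape:
            raise ConfigError(
                f"expected input shape {self.spec.input_shape}, got {x.shape[1:]}"
            )
        x = np.ascontiguousarray(x.transpose(1, 0, 2, 3))  # to channel-major
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Per-example ``[p_nonartifact, p_artifact]`` probabilities."""
        x = np.asarray(x, np.float32)
        if x.ndim == 3:
            x = x[None]
        out = np.empty((x.shape[0], 2), np.float32)
        for i in range(0, x.shape[0], batch_size):
            out[i : i + batch_size] = softmax(self.logits(x[i : i + batch_size]))
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate loss gradients; per-layer gradients are stored on the
        layers (the first layer skips its input gradient)."""
        d = np.asarray(dlogits, np.float32)
        last = len(self.layers) - 1
        for i, layer in enumerate(reversed(self.layers)):
            d = layer.backward(d, need_dx=i < last)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.gradients()]


def build_model(spec: ArchSpec = ArchSpec(), seed: int = 0) -> CNNModel:
    """Instantiate the network with seeded Kaiming-uniform weights."""
    return CNNModel(spec, seed)


def forward(model: CNNModel, batch: np.ndarray) -> np.ndarray:
    """Softmax probabilities ``[p_nonartifact, p_artifact]`` for a batch."""
    return model.predict_proba(batch)


def count_parameters(model: CNNModel) -> dict[str, int]:
    """Per-layer and total trainable parameter counts.

    Keys are ``conv1..conv3``, ``pool1..pool3``, ``fc`` and ``total``; ReLU
    activations are folded into their convolution.
    """
    counts: dict[str, int] = {}
    conv_i = pool_i = 0
    for layer in model.layers:
        if isinstance(layer, _ConvReLU):
            conv_i += 1
            counts[f"conv{conv_i}"] = sum(int(p.size) for p in layer.parameters())
        elif isinstance(layer, _MaxPool):
            pool_i += 1
            counts[f"pool{pool_i}"] = 0
        elif isinstance(layer, _Linear):
            counts["fc"] = sum(int(p.size) for p in layer.parameters())
    counts["total"] = sum(v for v in counts.values())
    return counts


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: CNNModel, path: str | Path, extra: dict | None = None) -> None:
    """Write weights plus a JSON description of the architecture and seed."""
    meta = {
        "format": "eegannot-checkpoint",
        "version": 1,
        "seed": model.seed,
        "input_shape": list(model.spec.input_shape),
        "layers": [_layer_desc(l) for l in model.spec.layers],
        "extra": extra or {},
    }
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def _layer_desc(layer) -> dict:
    if isinstance(layer, ConvSpec):
        return {
            "kind": "conv",
            "out_channels": layer.out_channels,
            "groups": layer.groups,
            "kernel": list(layer.kernel),
            "bias": layer.bias,
        }
    if isinstance(layer, PoolSpec):
        return {"kind": "pool", "kernel": list(layer.kernel)}
    if isinstance(layer, FCSpec):
        return {"kind": "fc", "out_features": layer.out_features, "bias": layer.bias}
    raise ConfigError(f"unknown layer {layer!r}")


def load_checkpoint(path: str | Path) -> tuple[CNNModel, dict]:
    """Rebuild a model from a checkpoint; returns ``(model, extra_metadata)``."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        layers: list = []
        for desc in meta["layers"]:
            if desc["kind"] == "conv":
                layers.append(
                    ConvSpec(desc["out_channels"], desc["groups"], tuple(desc["kernel"]), desc["bias"])
                )
            elif desc["kind"] == "pool":
                layers.append(PoolSpec(tuple(desc["kernel"])))
            elif desc["kind"] == "fc":
                layers.append(FCSpec(desc["out_features"], desc["bias"]))
        spec = ArchSpec(input_shape=tuple(meta["input_shape"]), layers=tuple(layers))
        model = CNNModel(spec, meta["seed"])
        for i, p in enumerate(model.parameters()):
            p[:] = data[f"param_{i}"]
    return model, meta["extra"]
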