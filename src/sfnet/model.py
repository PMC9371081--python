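"""The two-scale hybrid SFNet.

Two parallel convolutional feature extractors — one fed the grey radiograph,
one fed its edge map from the improved Canny detector — each a stack of
``conv -> ReLU -> batch-norm (-> LRN on the first two layers) -> 2x2 average
pool`` blocks with widths 16, 32, 64, 128, 256, 512 by default, closed by a
global average pool so each stream emits a 512-vector. The two stream vectors
A (grey) and V (edges) are fused by concatenation into a 1024-vector, then a
1024-unit dense layer, ReLU, dropout and a 2-unit dense layer with softmax
produce the fracture/healthy probabilities. The default build stays within a
5 x 10^6 trainable-parameter budget (~4.2M with 3x3 kernels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .image_io import ValidationError
from . import nn


@dataclass(frozen=True)
class LRNParams:
    """Hyper-parameters of local response normalization.

    ``t`` guards against division by zero, ``alpha`` scales the squared-sum,
    ``beta`` is the contrast exponent and ``n`` the channel window size.
    """

    t: float = 2.0
    alpha: float = 1e-4
    beta: float = 0.75
    n: int = 5

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"LRN n must be >= 1, got {self.n}")


@dataclass(frozen=True)
class SFNetConfig:
    """Architecture hyper-parameters.

    ``conv_widths`` must be strictly increasing; the default is the six-layer
    16..512 stack. ``input_side`` must survive one 2x2 pool per conv layer.
    ``lrn_after`` lists the (0-based) conv layers followed by LRN.
    """

    input_side: int = 256
    input_channels: int = 3
    conv_widths: tuple[int, ...] = (16, 32, 64, 128, 256, 512)
    kernel_side: int = 3
    pool_side: int = 2
    dense_units: int = 1024
    n_classes: int = 2
    dropout_rate: float = 0.5
    lrn: LRNParams = field(default_factory=LRNParams)
    lrn_after: tuple[int, ...] = (0, 1)

    def __post_init__(self) -> None:
        w = self.conv_widths
        if len(w) == 0 or any(b <= a for a, b in zip(w, w[1:])):
            raise ValidationError(f"conv_widths must be non-empty and strictly increasing, got {w}")
        if self.n_classes != 2:
            raise ValidationError("this classifier is strictly two-class")
        if self.kernel_side % 2 == 0 or self.kernel_side < 1:
            raise ValidationError(f"kernel_side must be odd, got {self.kernel_side}")
        if self.pool_side != 2:
            raise ValidationError("only 2x2 pooling is supported")
        if self.input_side % (2 ** len(w)) != 0:
            raise ValidationError(
                f"input_side {self.input_side} not divisible by 2^{len(w)} pools"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")

    @property
    def feature_dim(self) -> int:
        """Per-stream feature length after global average pooling."""
        return self.conv_widths[-1]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SFNetConfig":
        d = dict(d)
        if "lrn" in d and isinstance(d["lrn"], dict):
            d["lrn"] = LRNParams(**d["lrn"])
        for key in ("conv_widths", "lrn_after"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def reduced_config(side: int = 64) -> SFNetConfig:
    """A small build for desk-scale experiments: widths 8..64, 1 channel."""
    return SFNetConfig(
        input_side=side,
        input_channels=1,
        conv_widths=(8, 16, 32, 64),
        dense_units=128,
    )


def fuse_features(a: np.ndarray, v: np.ndarray, expected: int | None = 512) -> np.ndarray:
    """Concatenate the grey-stream vector A and edge-stream vector V, A first.

    ``expected`` pins the per-stream length (512 in the full model); pass
    ``None`` to accept any matching pair. Supports single vectors or batches.
    """
    a = np.asarray(a)
    v = np.asarray(v)
    if a.shape != v.shape:
        raise ValidationError(f"stream feature shapes differ: A {a.shape} vs V {v.shape}")
    if expected is not None and a.shape[-1] != expected:
        raise ValidationError(
            f"per-stream feature length {a.shape[-1]} != expected {expected}"
        )
    return np.concatenate([a, v], axis=-1)


class _Stream:
    """One convolutional feature extractor ending in a global average pool."""

    def __init__(self, cfg: SFNetConfig, rng: np.random.Generator):
        self.layers: list[nn.Layer] = []
        c_prev = cfg.input_channels
        for i, width in enumerate(cfg.conv_widths):
            self.layers.append(nn.Conv2d(c_prev, width, cfg.kernel_side, rng))
            self.layers.append(nn.ReLU())
            self.layers.append(nn.BatchNorm2d(width))
            if i in cfg.lrn_after:
                p = cfg.lrn
                self.layers.append(nn.LRN(t=p.t, alpha=p.alpha, beta=p.beta, n=p.n))
            self.layers.append(nn.AvgPool2())
            c_prev = width
        self.layers.append(nn.GlobalAvgPool())

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[nn.Param]:
        return [p for layer in self.layers for p in layer.parameters()]


class SFNet:
    """The assembled two-stream network.

    ``use_edge_stream=False`` builds the grey-only ablation: the edge stream
    is dropped and its half of the fused vector is zero, so the head keeps
    the same shape and only the grey half carries signal.
    """

    def __init__(self, config: SFNetConfig, seed: int = 0, use_edge_stream: bool = True):
        self.config = config
        self.use_edge_stream = use_edge_stream
        rng = np.random.default_rng(seed)
        self.stream_a = _Stream(config, rng)
        self.stream_v = _Stream(config, rng) if use_edge_stream else None
        fused = 2 * config.feature_dim
        self.dense1 = nn.Dense(fused, config.dense_units, rng)
        self.relu = nn.ReLU()
        self.dropout = nn.Dropout(config.dropout_rate, rng)
        self.dense2 = nn.Dense(config.dense_units, config.n_classes, rng)
        self._head = [self.dense1, self.relu, self.dropout, self.dense2]

    # -- forward / backward -------------------------------------------------

    def _expand(self, x: np.ndarray) -> np.ndarray:
        """(B, H, W) grey or edge batch -> (B, C, H, W) by channel replication."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = np.repeat(x[:, None], self.config.input_channels, axis=1)
        return x

    def features(self, grey: np.ndarray, edges: np.ndarray | None, train: bool = False):
        """Return (A, V, fused) feature batches."""
        a = self.stream_a.forward(self._expand(grey), train=train)
        if self.stream_v is not None:
            if edges is None:
                raise ValidationError("edge-stream model needs an edge-map batch")
            v = self.stream_v.forward(self._expand(edges), train=train)
        else:
            v = np.zeros_like(a)
        return a, v, fuse_features(a, v, expected=None)

    def forward(self, grey: np.ndarray, edges: np.ndarray | None, train: bool = False) -> np.ndarray:
        """Logits for a batch."""
        _, _, fused = self.features(grey, edges, train=train)
        h = fused
        for layer in self._head:
            h = layer.forward(h, train=train)
        return h

    def predict_proba(self, grey: np.ndarray, edges: np.ndarray | None) -> np.ndarray:
        return nn.softmax(self.forward(grey, edges, train=False))

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits.astype(np.float32)
        for layer in reversed(self._head):
            d = layer.backward(d)
        f = self.config.feature_dim
        self.stream_a.backward(d[:, :f])
        if self.stream_v is not None:
            self.stream_v.backward(d[:, f:])

    def parameters(self) -> list[nn.Param]:
        params = self.stream_a.parameters()
        if self.stream_v is not None:
            params += self.stream_v.parameters()
        for layer in self._head:
            params += layer.parameters()
        return params

    # -- persistence --------------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i}"] = p.value
        bn_id = 0
        for stream in filter(None, [self.stream_a, self.stream_v]):
            for layer in stream.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    arrays[f"bn_{bn_id}_mean"] = layer.running_mean
                    arrays[f"bn_{bn_id}_var"] = layer.running_var
                    bn_id += 1
        return arrays

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value = np.array(arrays[f"param_{i}"], dtype=np.float32)
        bn_id = 0
        for stream in filter(None, [self.stream_a, self.stream_v]):
            for layer in stream.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean = np.array(arrays[f"bn_{bn_id}_mean"], dtype=np.float32)
                    layer.running_var = np.array(arrays[f"bn_{bn_id}_var"], dtype=np.float32)
                    bn_id += 1


def build_sfnet(config: SFNetConfig = SFNetConfig(), seed: int = 0,
                use_edge_stream: bool = True) -> SFNet:
    """Instantiate the network with seeded He-normal initialization."""
    return SFNet(config, seed=seed, use_edge_stream=use_edge_stream)


def count_parameters(model: SFNet) -> int:
    """Exact count of trainable scalars (conv/dense weights and biases,
    batch-norm affine terms; running statistics excluded)."""
    return int(sum(p.value.size for p in model.parameters()))
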