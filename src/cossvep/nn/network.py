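"""Declarative architecture specs and their runtime networks.

An :class:`ArchitectureSpec` is an ordered stack of layer descriptors
(conv2d / flatten / dense / dropout) plus the spatial input shape
(channels x frequency bins) and the class count. Specs are pure data:
they can be shape-traced, parameter-counted, hashed and serialized to
JSON without ever allocating weights. :class:`Network` realizes a spec
as runtime layers (conv -> batch-norm -> ReLU chains, etc.) and is the
trained-model object the rest of the package passes around.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import layers as L

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "Network",
    "forward",
    "cross_entropy",
    "shape_trace",
    "count_parameters",
]


class ConfigurationError(ValueError):
    """Raised when an architecture cannot be realized (untraceable shapes etc.)."""


@dataclass(frozen=True)
class LayerSpec:
    """One descriptor in the stack.

    ``kind`` is one of conv2d / flatten / dense / dropout. Convolutions
    carry ``filters``, ``kernel`` (rows, cols), ``padding`` ('preserve'
    keeps the convolved axis length via zero padding, 'valid' shrinks it),
    ``batch_norm`` and ``activation``; dense layers carry ``units`` and
    ``activation``; dropout carries ``rate``.
    """

    kind: str
    filters: int = 0
    kernel: tuple[int, int] = (0, 0)
    padding: str = "valid"
    activation: str = "none"
    batch_norm: bool = False
    units: int = 0
    rate: float = 0.0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "filters": self.filters,
            "kernel": list(self.kernel),
            "padding": self.padding,
            "activation": self.activation,
            "batch_norm": self.batch_norm,
            "units": self.units,
            "rate": self.rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayerSpec":
        d = dict(d)
        d["kernel"] = tuple(d.get("kernel", (0, 0)))
        return cls(**d)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Full network description: input geometry, layer stack, class count."""

    input_shape: tuple[int, int]
    layers: tuple[LayerSpec, ...]
    n_classes: int = 4
    name: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_shape": list(self.input_shape),
                "layers": [l.to_dict() for l in self.layers],
                "n_classes": self.n_classes,
                "name": self.name,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        return cls(
            input_shape=tuple(d["input_shape"]),
            layers=tuple(LayerSpec.from_dict(l) for l in d["layers"]),
            n_classes=d["n_classes"],
            name=d.get("name", ""),
        )

    def spec_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    @property
    def conv_indices(self) -> tuple[int, ...]:
        return tuple(i for i, l in enumerate(self.layers) if l.kind == "conv2d")


def shape_trace(spec: ArchitectureSpec) -> list[tuple[int, int]]:
    """Spatial (rows, cols) shape of the input and of each conv output.

    Reproduces the feature-size column of the printed architecture
    tables: one entry for the input plus one per convolution. Raises
    :class:`ConfigurationError` if any kernel does not fit.
    """
    h, w = spec.input_shape
    trace = [(h, w)]
    for l in spec.layers:
        if l.kind != "conv2d":
            continue
        kh, kw = l.kernel
        if l.padding == "valid":
            h, w = h - kh + 1, w - kw + 1
        if h < 1 or w < 1:
            raise ConfigurationError(
                f"kernel {l.kernel} leaves a non-positive map {h}x{w}; "
                f"input {spec.input_shape} is too small for this stack"
            )
        trace.append((h, w))
    return trace


def count_parameters(spec: ArchitectureSpec) -> int:
    """Trainable parameter count (conv/dense weights+biases, BN scale+shift)."""
    total = 0
    channels = 1
    h, w = spec.input_shape
    flat: int | None = None
    for l in spec.layers:
        if l.kind == "conv2d":
            kh, kw = l.kernel
            total += channels * kh * kw * l.filters + l.filters
            if l.batch_norm:
                total += 2 * l.filters
            if l.padding == "valid":
                h, w = h - kh + 1, w - kw + 1
            if h < 1 or w < 1:
                raise ConfigurationError("untraceable spec: kernel exceeds feature map")
            channels = l.filters
        elif l.kind == "flatten":
            flat = channels * h * w
        elif l.kind == "dense":
            if flat is None:
                raise ConfigurationError("dense layer before flatten")
            total += flat * l.units + l.units
            flat = l.units
        elif l.kind == "dropout":
            continue
        else:
            raise ConfigurationError(f"unknown layer kind {l.kind!r}")
    return total


class Network:
    """A realized (trainable) network: spec + parameters + freeze flags.

    The final dense layer's softmax is applied inside :meth:`forward`;
    the class-probability rows it returns are non-negative and sum to 1.
    """

    def __init__(self, spec: ArchitectureSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        self.frozen_layers: set[int] = set()
        init_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
        self.dropout_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(2,))
        )
        self.ops: list[L.Layer] = []
        channels, (h, w) = 1, spec.input_shape
        flat: int | None = None
        for idx, l in enumerate(spec.layers):
            if l.kind == "conv2d":
                conv = L.Conv2D(channels, l.filters, l.kernel, l.padding, rng=init_rng)
                try:
                    h, w = conv.output_shape(h, w)
                except ValueError as exc:
                    raise ConfigurationError(str(exc)) from exc
                ops = [conv]
                if l.batch_norm:
                    ops.append(L.BatchNorm2D(l.filters))
                if l.activation == "relu":
                    ops.append(L.ReLU())
                channels = l.filters
            elif l.kind == "flatten":
                flat = channels * h * w
                ops = [L.Flatten()]
            elif l.kind == "dense":
                if flat is None:
                    raise ConfigurationError("dense layer before flatten")
                dense = L.Dense(flat, l.units, rng=init_rng)
                flat = l.units
                ops = [dense]
                if l.activation == "relu":
                    ops.append(L.ReLU())
            elif l.kind == "dropout":
                drop = L.Dropout(l.rate)
                drop.rng = self.dropout_rng
                ops = [drop]
            else:
                raise ConfigurationError(f"unknown layer kind {l.kind!r}")
            for op in ops:
                op.spec_index = idx
                self.ops.append(op)
        if flat != spec.n_classes:
            raise ConfigurationError(
                f"stack ends in {flat} outputs, expected n_classes={spec.n_classes}"
            )

    # ------------------------------------------------------------------ shapes
    def _check_batch(self, batch: np.ndarray) -> np.ndarray:
        x = np.asarray(batch, dtype=L.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None, :, :]
        expected = self.spec.input_shape
        if x.shape[2:] != expected or x.shape[1] != 1:
            raise ValueError(
                f"batch shape {tuple(np.shape(batch))} incompatible with network "
                f"input {expected} (expected (n, {expected[0]}, {expected[1]}))"
            )
        return x

    # ----------------------------------------------------------------- forward
    def forward_logits(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._check_batch(batch)
        for op in self.ops:
            x = op.forward(x, training=training)
        return x

    def forward(self, batch: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities, one row per example (softmax output)."""
        return L.softmax(self.forward_logits(batch, training=training))

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(batch), axis=1)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits.astype(L.DTYPE)
        for op in reversed(self.ops):
            g = op.backward(g)

    # -------------------------------------------------------------- parameters
    def named_parameters(self, trainable_only: bool = False):
        """Yield (name, layer, key, array) for every parameter tensor."""
        for i, op in enumerate(self.ops):
            if trainable_only and op.spec_index in self.frozen_layers:
                continue
            for key, arr in op.params().items():
                yield f"op{i}.{key}", op, key, arr

    def set_frozen(self, spec_indices: set[int]) -> None:
        self.frozen_layers = set(spec_indices)
        for op in self.ops:
            op.frozen = op.spec_index in self.frozen_layers

    def parameter_snapshot(self, spec_indices: set[int] | None = None) -> dict[str, np.ndarray]:
        """Copies of parameter + state tensors, optionally restricted to layers."""
        out = {}
        for i, op in enumerate(self.ops):
            if spec_indices is not None and op.spec_index not in spec_indices:
                continue
            for key, arr in {**op.params(), **op.state()}.items():
                out[f"op{i}.{key}"] = arr.copy()
        return out

    def state_tensors(self) -> dict[str, np.ndarray]:
        out = {}
        for i, op in enumerate(self.ops):
            for key, arr in {**op.params(), **op.state()}.items():
                out[f"op{i}.{key}"] = arr
        return out

    def load_state(self, tensors: dict[str, np.ndarray]) -> None:
        own = self.state_tensors()
        if set(own) != set(tensors):
            raise ValueError("state tensor names do not match this architecture")
        for name, arr in own.items():
            arr[...] = tensors[name]


def forward(model: Network, batch: np.ndarray) -> np.ndarray:
    """Evaluation-mode class probabilities for a batch of feature matrices."""
    return model.forward(batch, training=False)


def cross_entropy(probabilities: np.ndarray, one_hot_labels: np.ndarray) -> float:
    """Mean categorical cross-entropy, natural log, probabilities clipped at 1e-12."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(one_hot_labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probabilities {p.shape}, labels {y.shape}")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    is_binary = np.all((y == 0) | (y == 1))
    if not is_binary or not np.all(y.sum(axis=1) == 1):
        raise ValueError("labels must be one-hot")
    p = np.clip(p, 1e-12, 1.0)
    return float(np.mean(-np.sum(y * np.log(p), axis=1)))


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((labels.shape[0], n_classes), dtype=np.float64)
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out
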