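"""Two-stage transfer-learning protocol for the SSVEP classifiers.

Stage 1 (*pretrain*): train every layer with Adam (learning rate 0.001,
80 epochs, mini-batches of 16) on a large source domain, minimizing
categorical cross-entropy. Stage 2 (*fine-tune*): freeze the shallow
half of the convolutional stack — the generic spatial/spectral feature
extractor — and re-train only the deep convolutions and the dense head
on a small target set at a reduced learning rate (1e-4, 40 epochs).

Freezing is total: frozen layers receive no gradient updates and their
batch-norm statistics stop adapting, so their tensors are bit-identical
before and after fine-tuning.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, replace

import numpy as np

from .nn.network import ArchitectureSpec, ConfigurationError, Network, one_hot
from .nn import layers as L

__all__ = [
    "TrainConfig",
    "IntegrityError",
    "pretrain",
    "train_from_scratch",
    "freeze_shallow",
    "finetune",
    "save_checkpoint",
    "load_checkpoint",
    "TransferPipeline",
    "load_thu_benchmark",
]


class IntegrityError(RuntimeError):
    """A checkpoint failed validation (corruption or spec mismatch)."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for one training stage (optimizer: Adam)."""

    stage: str = "pretrain"
    learning_rate: float = 1e-3
    epochs: int = 80
    batch_size: int = 16
    seed: int = 0
    freeze_policy: str = "none"

    def __post_init__(self) -> None:
        if self.stage not in ("pretrain", "finetune"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.learning_rate <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("need learning_rate > 0, epochs >= 1, batch_size >= 1")

    @classmethod
    def for_pretrain(cls, seed: int = 0, **overrides) -> "TrainConfig":
        return replace(cls(stage="pretrain", learning_rate=1e-3, epochs=80, seed=seed), **overrides)

    @classmethod
    def for_finetune(cls, seed: int = 0, **overrides) -> "TrainConfig":
        return replace(
            cls(stage="finetune", learning_rate=1e-4, epochs=40,
                freeze_policy="first_half_convs", seed=seed),
            **overrides,
        )


class _Adam:
    """Adam optimizer over a network's trainable (unfrozen) tensors."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, model: Network) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for name, op, key, arr in model.named_parameters(trainable_only=True):
            g = op.grads()[key]
            if name not in self.m:
                self.m[name] = np.zeros_like(arr)
                self.v[name] = np.zeros_like(arr)
            self.m[name] = self.beta1 * self.m[name] + (1 - self.beta1) * g
            self.v[name] = self.beta2 * self.v[name] + (1 - self.beta2) * g * g
            mhat = self.m[name] / b1t
            vhat = self.v[name] / b2t
            arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(arr.dtype)


def _fit(model: Network, X: np.ndarray, y: np.ndarray, config: TrainConfig) -> Network:
    """Mini-batch Adam on softmax cross-entropy; deterministic given seed."""
    X = np.asarray(X, dtype=L.DTYPE)
    y = np.asarray(y, dtype=int)
    if X.shape[1:] != model.spec.input_shape:
        raise ValueError(
            f"feature shape {X.shape[1:]} does not match network input "
            f"{model.spec.input_shape}"
        )
    if not any(True for _ in model.named_parameters(trainable_only=True)):
        raise ConfigurationError("no trainable parameters (all layers frozen)")
    targets = one_hot(y, model.spec.n_classes)
    n = X.shape[0]
    opt = _Adam(config.learning_rate)
    shuffle_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(3,))
    )
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward_logits(X[idx], training=True)
            probs = _softmax64(logits)
            grad = (probs - targets[idx]) / idx.shape[0]
            model.backward(grad)
            opt.step(model)
    return model


def _softmax64(logits: np.ndarray) -> np.ndarray:
    z = logits.astype(np.float64)
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def pretrain(
    spec: ArchitectureSpec, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None
) -> Network:
    """Stage-1 training of a freshly initialized network on the source domain."""
    if config is None:
        config = TrainConfig.for_pretrain()
    if config.stage != "pretrain":
        raise ValueError("pretrain requires a config with stage='pretrain'")
    model = Network(spec, seed=config.seed)
    return _fit(model, X, y, config)


def train_from_scratch(
    spec: ArchitectureSpec, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None
) -> Network:
    """Direct training without a source domain (the no-transfer baseline)."""
    if config is None:
        config = TrainConfig.for_pretrain()
    model = Network(spec, seed=config.seed)
    return _fit(model, X, y, replace(config, stage="pretrain"))


def freeze_shallow(model: Network, policy: str = "first_half_convs") -> Network:
    """Mark shallow layers as frozen according to a named policy.

    ``first_half_convs`` freezes the first half of the convolutional
    stack (2 of 4 convs for the single/serial nets, 3 of 6 for the
    two-person parallel net); ``none`` clears the frozen set.
    """
    conv_idx = model.spec.conv_indices
    if policy == "first_half_convs":
        frozen = set(conv_idx[: len(conv_idx) // 2])
    elif policy == "none":
        frozen = set()
    else:
        raise ConfigurationError(f"unknown freeze policy {policy!r}")
    model.set_frozen(frozen)
    return model


def finetune(
    model: Network, X: np.ndarray, y: np.ndarray, config: TrainConfig | None = None
) -> Network:
    """Stage-2 training of the unfrozen layers; optimizer state starts fresh.

    The model is trained in place and returned. Frozen-layer tensors
    (weights, biases, batch-norm scale/shift and running statistics) are
    untouched.
    """
    if config is None:
        config = TrainConfig.for_finetune()
    if config.stage != "finetune":
        raise ValueError("finetune requires a config with stage='finetune'")
    if config.freeze_policy != "keep":
        freeze_shallow(model, config.freeze_policy)
    return _fit(model, X, y, config)


# --------------------------------------------------------------------- checkpoints

def save_checkpoint(model: Network, path) -> None:
    """Serialize spec, parameters, batch-norm state and freeze flags to .npz."""
    tensors = model.state_tensors()
    payload = b"".join(np.ascontiguousarray(tensors[k]).tobytes() for k in sorted(tensors))
    np.savez(
        path,
        __spec_json__=np.frombuffer(model.spec.to_json().encode(), dtype=np.uint8),
        __spec_hash__=np.frombuffer(model.spec.spec_hash().encode(), dtype=np.uint8),
        __checksum__=np.frombuffer(hashlib.sha256(payload).hexdigest().encode(), dtype=np.uint8),
        __frozen__=np.array(sorted(model.frozen_layers), dtype=np.int64),
        __seed__=np.array([model.seed], dtype=np.int64),
        **tensors,
    )


def load_checkpoint(path, expected_spec: ArchitectureSpec | None = None) -> Network:
    """Reconstruct a :class:`Network` from a checkpoint, verifying integrity."""
    try:
        with np.load(path) as data:
            blobs = {k: data[k] for k in data.files}
    except Exception as exc:  # unreadable / truncated file
        raise IntegrityError(f"cannot read checkpoint {path}: {exc}") from exc
    try:
        spec = ArchitectureSpec.from_json(bytes(blobs.pop("__spec_json__")).decode())
        stored_hash = bytes(blobs.pop("__spec_hash__")).decode()
        checksum = bytes(blobs.pop("__checksum__")).decode()
        frozen = set(int(i) for i in blobs.pop("__frozen__"))
        seed = int(blobs.pop("__seed__")[0])
    except Exception as exc:
        raise IntegrityError(f"checkpoint {path} is malformed: {exc}") from exc
    if spec.spec_hash() != stored_hash:
        raise IntegrityError(
            f"spec hash mismatch in {path}: stored {stored_hash}, "
            f"recomputed {spec.spec_hash()}"
        )
    if expected_spec is not None and expected_spec.spec_hash() != stored_hash:
        raise IntegrityError(
            f"checkpoint spec hash {stored_hash} does not match expected "
            f"{expected_spec.spec_hash()}"
        )
    payload = b"".join(np.ascontiguousarray(blobs[k]).tobytes() for k in sorted(blobs))
    if hashlib.sha256(payload).hexdigest() != checksum:
        raise IntegrityError(f"parameter checksum mismatch in {path}")
    model = Network(spec, seed=seed)
    model.load_state(blobs)
    model.set_frozen(frozen)
    return model


class TransferPipeline:
    """Fold-level fit/predict wrapper around a shared pretrained checkpoint.

    Each :meth:`fit` deep-copies the pretrained model (never the other
    way around), applies the freeze policy, and fine-tunes on the fold's
    training split only.
    """

    def __init__(
        self,
        pretrained: Network,
        finetune_config: TrainConfig | None = None,
    ) -> None:
        self.pretrained = pretrained
        self.finetune_config = finetune_config or TrainConfig.for_finetune()
        self.model: Network | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TransferPipeline":
        self.model = finetune(copy.deepcopy(self.pretrained), X, y, self.finetune_config)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("pipeline is not fitted")
        return self.model.predict(X)


def load_thu_benchmark(root, subjects=None):  # pragma: no cover - convenience stub
    """Loader stub for the public 40-target SSVEP benchmark corpus.

    Expected layout under ``root``: one MATLAB v7.3 file per subject
    (``S1.mat`` ... ``S35.mat``), each holding a ``data`` array of shape
    (64 electrodes, samples, 40 targets, 6 blocks) at 250 Hz, plus
    ``Freq_Phase.mat`` with the target frequency/phase tables. A user
    supplying the corpus would map the occipital rows (O1/Oz/O2) into
    :class:`~cossvep.simulate.RawEpoch` objects and resample to the
    paradigm rate. The corpus is not bundled and this loader is an
    untested convenience; it raises until pointed at real files.
    """
    raise NotImplementedError(
        "the benchmark corpus is not bundled; see the docstring for the "
        "expected on-disk layout"
    )
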