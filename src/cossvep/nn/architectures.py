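"""Builders for the compact SSVEP classifier family.

Three architectures share a design idiom inherited from compact
EEG-decoding networks (EEGNet and its descendants): narrow (k,1)
convolutions first learn spatial combinations across electrode "leads"
and collapse them to a single channel, then (1,k) convolutions act as
learned band-pass filters along the spectrum; a small dense head with
dropout performs the 4-class decision.

* single-person: 3 x B input, 4 convs (16, 32, 32, 64 filters);
* parallel fusion (K subjects): 3K x B input, a deeper channel-collapsing
  stack — for K = 2: 16, 32, 64, 64, 128, 256 filters;
* serial fusion (K subjects): 3 x (K*B) input, the single-person stack
  with filter counts scaled up — for K = 2: 48, 96, 96, 192.

Every conv carries batch normalization and ReLU; the head is
flatten -> dense(8) -> dropout(0.5) -> dense(4, softmax).
"""

from __future__ import annotations

from .network import ArchitectureSpec, ConfigurationError, LayerSpec

__all__ = ["build_single_cnn", "build_parallel_cnn", "build_serial_cnn", "build"]


def _conv(filters: int, kernel: tuple[int, int], padding: str) -> LayerSpec:
    return LayerSpec(
        kind="conv2d",
        filters=filters,
        kernel=kernel,
        padding=padding,
        activation="relu",
        batch_norm=True,
    )


def _head() -> tuple[LayerSpec, ...]:
    return (
        LayerSpec(kind="flatten"),
        LayerSpec(kind="dense", units=8),
        LayerSpec(kind="dropout", rate=0.5),
        LayerSpec(kind="dense", units=4, activation="softmax"),
    )


def build_single_cnn(input_shape: tuple[int, int] = (3, 78)) -> ArchitectureSpec:
    """Single-person network for a 3 x B spectral feature matrix.

    Stack: conv 16x(3,1) preserve -> conv 32x(3,1) valid (collapses the
    three electrodes to one channel) -> conv 32x(1,3) preserve ->
    conv 64x(1,3) valid -> head.
    """
    rows, bins = input_shape
    if rows != 3:
        raise ConfigurationError(f"single-person network expects 3 channel rows, got {rows}")
    if bins < 5:
        raise ConfigurationError(f"need at least 5 frequency bins, got {bins}")
    layers = (
        _conv(16, (3, 1), "preserve"),
        _conv(32, (3, 1), "valid"),
        _conv(32, (1, 3), "preserve"),
        _conv(64, (1, 3), "valid"),
        *_head(),
    )
    return ArchitectureSpec(input_shape=input_shape, layers=layers, name="single")


def build_parallel_cnn(
    n_subjects: int = 2, input_shape: tuple[int, int] | None = None
) -> ArchitectureSpec:
    """Parallel-fusion network for a (3K) x B stacked feature matrix.

    For K = 2 this is exactly: conv 16x(6,1) preserve -> conv 32x(3,1)
    valid -> conv 64x(3,1) valid -> conv 64x(2,1) valid -> conv 128x(1,3)
    preserve -> conv 256x(1,3) valid -> head, tracing the channel axis
    6 -> 6 -> 4 -> 2 -> 1 -> 1 -> 1.

    For K > 2 the same recipe generalizes: a full-height (3K,1) preserve
    conv, then (3,1) valid convs doubling filters until at most two
    channel rows remain, a final (remaining,1) valid collapse at the same
    width, and the two (1,3) spectral convs doubling filters twice more.
    """
    if n_subjects < 2:
        raise ConfigurationError(
            "parallel-fusion network needs >= 2 subjects; use build_single_cnn for one"
        )
    rows = 3 * n_subjects
    if input_shape is None:
        input_shape = (rows, 78)
    if input_shape[0] != rows:
        raise ConfigurationError(
            f"input rows {input_shape[0]} inconsistent with {n_subjects} subjects "
            f"(expected {rows})"
        )
    if input_shape[1] < 5:
        raise ConfigurationError(f"need at least 5 frequency bins, got {input_shape[1]}")

    layers = [_conv(16, (rows, 1), "preserve")]
    filters = 16
    remaining = rows
    while remaining > 2:
        filters *= 2
        layers.append(_conv(filters, (3, 1), "valid"))
        remaining -= 2
    if remaining == 2:
        layers.append(_conv(filters, (2, 1), "valid"))
        remaining = 1
    filters *= 2
    layers.append(_conv(filters, (1, 3), "preserve"))
    filters *= 2
    layers.append(_conv(filters, (1, 3), "valid"))
    return ArchitectureSpec(
        input_shape=input_shape, layers=(*layers, *_head()), name=f"parallel{n_subjects}"
    )


def build_serial_cnn(
    n_subjects: int = 2, input_shape: tuple[int, int] | None = None
) -> ArchitectureSpec:
    """Serial-fusion network for a 3 x (K*B) concatenated feature matrix.

    The single-person stack with filter counts multiplied by (2K - 1):
    for K = 2 that is 48, 96, 96, 192, compensating the widened spectrum
    with more feature extractors per layer.
    """
    if n_subjects < 2:
        raise ConfigurationError(
            "serial-fusion network needs >= 2 subjects; use build_single_cnn for one"
        )
    if input_shape is None:
        input_shape = (3, 78 * n_subjects)
    if input_shape[0] != 3:
        raise ConfigurationError(
            f"serial fusion keeps 3 channel rows, got {input_shape[0]}"
        )
    if input_shape[1] < 5:
        raise ConfigurationError(f"need at least 5 frequency bins, got {input_shape[1]}")
    s = 2 * n_subjects - 1
    layers = (
        _conv(16 * s, (3, 1), "preserve"),
        _conv(32 * s, (3, 1), "valid"),
        _conv(32 * s, (1, 3), "preserve"),
        _conv(64 * s, (1, 3), "valid"),
        *_head(),
    )
    return ArchitectureSpec(
        input_shape=input_shape, layers=layers, name=f"serial{n_subjects}"
    )


def build(arch: str, n_subjects: int = 1, bins: int = 78) -> ArchitectureSpec:
    """Build by name: 'single', 'parallel' or 'serial'.

    The 'average' fusion mode reuses the single-person architecture.
    """
    if arch in ("single", "average"):
        return build_single_cnn((3, bins))
    if arch == "parallel":
        return build_parallel_cnn(n_subjects, (3 * n_subjects, bins))
    if arch == "serial":
        return build_serial_cnn(n_subjects, (3, bins * n_subjects))
    raise ConfigurationError(f"unknown architecture {arch!r}")
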