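"""Closed-form trainable-parameter counting for CNN architectures.

No deep-learning framework: each layer kind has an exact integer formula
(conv: ``kh·kw·c_in·filters + filters``; dense: ``n_in·units + units``;
pooling / dropout / flatten: 0) and a shape rule (valid convolutions shrink
spatial dims by ``kernel − 1``, same-padding keeps them, max pooling floors
by the stride).  ``model1_spec`` and ``vgg19_spec`` encode the two patch
classifiers whose published totals (1,661,186 and 20,024,897 trainable
weights) serve as transcription cross-checks: Model1's total is only
reproduced under valid padding, and VGG19's only with a global average
pool reducing the final 3×3×512 activation to the 512-vector feeding its
single-sigmoid head.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

LAYER_KINDS = ("input", "conv", "maxpool", "globalpool", "flatten", "dense", "dropout")


class ShapeError(ValueError):
    """A layer cannot be applied to the incoming activation shape."""


@dataclasses.dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor; fields irrelevant to ``kind`` are ignored.

    ``units`` is the filter count for conv layers and the neuron count for
    dense layers.  ``activation`` is metadata only.
    """

    kind: str
    units: int = 0
    kernel: tuple[int, int] = (3, 3)
    stride: tuple[int, int] | None = None
    padding: str = "valid"
    activation: str = ""

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ShapeError(f"unknown layer kind {self.kind!r}")
        if self.padding not in ("valid", "same"):
            raise ShapeError(f"unknown padding {self.padding!r}")


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer list starting from an input layer."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (96, 96, 3)

    def __post_init__(self) -> None:
        if not self.layers or self.layers[0].kind != "input":
            raise ShapeError("the first layer must be the input layer")


def layer_forward(
    spec: LayerSpec, in_shape: Sequence[int]
) -> tuple[int, tuple[int, ...]]:
    """Exact parameter count and output shape of one layer.

    Spatial shapes are ``(h, w, c)``; a flattened activation is ``(n,)``.
    """
    in_shape = tuple(int(d) for d in in_shape)
    if any(d <= 0 for d in in_shape):
        raise ShapeError(f"non-positive dimensions in shape {in_shape}")

    if spec.kind == "input":
        return 0, in_shape

    if spec.kind == "conv":
        if len(in_shape) != 3:
            raise ShapeError(f"conv needs an (h, w, c) input, got {in_shape}")
        h, w, c = in_shape
        kh, kw = spec.kernel
        if spec.padding == "valid":
            if kh > h or kw > w:
                raise ShapeError(
                    f"kernel {spec.kernel} larger than input {(h, w)} under "
                    "valid padding"
                )
            out_h, out_w = h - kh + 1, w - kw + 1
        else:
            out_h, out_w = h, w
        params = kh * kw * c * spec.units + spec.units
        return params, (out_h, out_w, spec.units)

    if spec.kind == "maxpool":
        if len(in_shape) != 3:
            raise ShapeError(f"maxpool needs an (h, w, c) input, got {in_shape}")
        h, w, c = in_shape
        sh, sw = spec.stride if spec.stride is not None else spec.kernel
        return 0, (h // sh, w // sw, c)

    if spec.kind == "globalpool":
        if len(in_shape) != 3:
            raise ShapeError(f"globalpool needs an (h, w, c) input, got {in_shape}")
        return 0, (in_shape[2],)

    if spec.kind == "flatten":
        n = 1
        for d in in_shape:
            n *= d
        return 0, (n,)

    if spec.kind == "dense":
        if len(in_shape) != 1:
            raise ShapeError(
                f"dense needs a flat (n,) input, got {in_shape}; insert a "
                "flatten or global pooling layer"
            )
        return in_shape[0] * spec.units + spec.units, (spec.units,)

    if spec.kind == "dropout":
        return 0, in_shape

    raise ShapeError(f"unknown layer kind {spec.kind!r}")  # pragma: no cover


def model_param_count(arch: ArchitectureSpec) -> int:
    """Total trainable parameters: layer_forward summed while threading
    shapes through the network."""
    shape: tuple[int, ...] = arch.input_shape
    total = 0
    for layer in arch.layers:
        params, shape = layer_forward(layer, shape)
        total += params
    return total


def _conv(filters: int, padding: str) -> LayerSpec:
    return LayerSpec(kind="conv", units=filters, kernel=(3, 3), padding=padding,
                     activation="relu")


def model1_spec() -> ArchitectureSpec:
    """The custom 9-convolution patch classifier (valid padding)."""
    pool = LayerSpec(kind="maxpool", kernel=(2, 2))
    drop = LayerSpec(kind="dropout")
    layers = (
        LayerSpec(kind="input"),
        _conv(32, "valid"), _conv(32, "valid"), _conv(32, "valid"), pool, drop,
        _conv(64, "valid"), _conv(64, "valid"), _conv(64, "valid"), pool,
        _conv(128, "valid"), _conv(128, "valid"), _conv(128, "valid"), pool,
        LayerSpec(kind="flatten"),
        LayerSpec(kind="dense", units=256, activation="relu"),
        drop,
        LayerSpec(kind="dense", units=2, activation="softmax"),
    )
    return ArchitectureSpec(layers=layers)


def vgg19_spec() -> ArchitectureSpec:
    """VGG19 feature stack (16 convolutions, same padding, stride-2 pools)
    with a global average pool ahead of the single-sigmoid dense head."""
    pool = LayerSpec(kind="maxpool", kernel=(2, 2), stride=(2, 2))
    blocks = [(64, 2), (128, 2), (256, 4), (512, 4), (512, 4)]
    layers: list[LayerSpec] = [LayerSpec(kind="input")]
    for filters, reps in blocks:
        layers.extend(_conv(filters, "same") for _ in range(reps))
        layers.append(pool)
    layers.append(LayerSpec(kind="globalpool"))
    layers.append(LayerSpec(kind="dense", units=1, activation="sigmoid"))
    return ArchitectureSpec(layers=tuple(layers))


ARCHITECTURES = {"model1": model1_spec, "vgg19": vgg19_spec}
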