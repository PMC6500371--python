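"""Declarative classifier architectures.

Three pixel classifiers are specified here as data, independent of any
particular tensor backend:

* **ERISNet** — nine 1D convolutional blocks (conv → ReLU → batch norm →
  dropout, L2 penalty on the conv weights) whose (filters, kernel)
  sequence repeats the motif (64, 8), (128, 5), (128, 3) three times,
  followed by two 64-unit LSTM blocks (the first emitting the full
  sequence, the second its final state), each batch-normalized, and a
  2-way softmax head.
* **MLP** — three 500-unit ReLU hidden layers with dropout
  (0.2, 0.2, 0.3) and a 2-way softmax head.
* **FCN** — three convolutional blocks (128, 8), (256, 5), (128, 3) in
  conv → batch norm → ReLU order, global average pooling, softmax head.

The specs carry enough structure to (a) build a trainable network
(:func:`sargnet.nn.build`), (b) count trainable parameters in closed
form, and (c) round-trip through YAML/JSON for reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import yaml


class ConfigurationError(ValueError):
    """An architecture spec violates its structural contract."""


#: Input layouts for the 14 reflectance attributes: one 14-long signal
#: with a single channel, or the rhos/rhot families as two channels of a
#: 7-long signal.
SUPPORTED_LAYOUTS = ((14, 1), (7, 2))


@dataclass(frozen=True)
class ConvBlockSpec:
    """1D convolution unit: conv (+ optional ReLU/BN/dropout/L2)."""

    n_filters: int
    kernel_size: int
    activation: str = "relu"
    batch_norm: bool = True
    dropout_rate: float = 0.0
    l2_coefficient: float = 0.0
    #: Component order inside the block; ERISNet lists its components as
    #: conv, ReLU, batch norm, dropout, while the FCN equations put
    #: batch norm before the activation.
    order: str = "conv_relu_bn_dropout"

    def __post_init__(self) -> None:
        if self.n_filters < 1 or self.kernel_size < 1:
            raise ConfigurationError("n_filters and kernel_size must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.l2_coefficient < 0:
            raise ConfigurationError("l2_coefficient must be >= 0")
        if self.order not in ("conv_relu_bn_dropout", "conv_bn_relu"):
            raise ConfigurationError(f"unknown block order {self.order!r}")


@dataclass(frozen=True)
class RecurrentBlockSpec:
    """LSTM unit; ``emits_sequence`` is True for every block but the last."""

    n_units: int = 64
    batch_norm: bool = True
    emits_sequence: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")


@dataclass(frozen=True)
class DenseBlockSpec:
    """Fully connected unit; the classification head uses softmax."""

    n_units: int
    activation: str = "relu"
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ConfigurationError("n_units must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.activation not in ("relu", "softmax"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    input_layout: tuple[int, int]
    conv_blocks: tuple[ConvBlockSpec, ...] = ()
    recurrent_blocks: tuple[RecurrentBlockSpec, ...] = ()
    dense_blocks: tuple[DenseBlockSpec, ...] = ()
    #: Pool the sequence axis to one feature vector before the dense
    #: head (the FCN's global average pooling).
    global_average_pool: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_layout", tuple(self.input_layout))
        object.__setattr__(self, "conv_blocks", tuple(self.conv_blocks))
        object.__setattr__(self, "recurrent_blocks", tuple(self.recurrent_blocks))
        object.__setattr__(self, "dense_blocks", tuple(self.dense_blocks))
        if not self.dense_blocks:
            raise ConfigurationError("an architecture needs a classification head")
        head = self.dense_blocks[-1]
        if head.activation != "softmax" or head.n_units != 2:
            raise ConfigurationError(
                "the final dense block must be a 2-unit softmax head"
            )
        if self.recurrent_blocks:
            for block in self.recurrent_blocks[:-1]:
                if not block.emits_sequence:
                    raise ConfigurationError(
                        "only the last recurrent block may collapse the sequence"
                    )
            if self.recurrent_blocks[-1].emits_sequence:
                raise ConfigurationError("the last recurrent block must emit its final state")

    @property
    def n_features(self) -> int:
        length, channels = self.input_layout
        return length * channels

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ArchitectureSpec":
        return cls(
            name=data["name"],
            input_layout=tuple(data["input_layout"]),
            conv_blocks=tuple(ConvBlockSpec(**b) for b in data.get("conv_blocks", ())),
            recurrent_blocks=tuple(
                RecurrentBlockSpec(**b) for b in data.get("recurrent_blocks", ())
            ),
            dense_blocks=tuple(DenseBlockSpec(**b) for b in data.get("dense_blocks", ())),
            global_average_pool=data.get("global_average_pool", False),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _check_layout(input_layout) -> tuple[int, int]:
    layout = tuple(input_layout)
    if layout not in SUPPORTED_LAYOUTS:
        raise ConfigurationError(
            f"unsupported input layout {layout!r}; expected one of {SUPPORTED_LAYOUTS}"
        )
    return layout


#: The printed filter/kernel motif; ERISNet's nine conv blocks repeat it
#: three times.
ERISNET_CONV_MOTIF: tuple[tuple[int, int], ...] = ((64, 8), (128, 5), (128, 3))


def erisnet_spec(
    input_layout=(14, 1),
    dropout_rate: float = 0.2,
    l2_coefficient: float = 1e-3,
) -> ArchitectureSpec:
    """ERISNet: 9 conv blocks + 2 LSTM blocks + softmax head.

    Every conv block carries ReLU, batch normalization, dropout and an
    L2 weight penalty; the dropout rate and L2 coefficient were not
    published and default to 0.2 and 1e-3.
    """
    layout = _check_layout(input_layout)
    conv = tuple(
        ConvBlockSpec(
            n_filters=f, kernel_size=k, activation="relu", batch_norm=True,
            dropout_rate=dropout_rate, l2_coefficient=l2_coefficient,
            order="conv_relu_bn_dropout",
        )
        for f, k in ERISNET_CONV_MOTIF * 3
    )
    recurrent = (
        RecurrentBlockSpec(n_units=64, batch_norm=True, emits_sequence=True),
        RecurrentBlockSpec(n_units=64, batch_norm=True, emits_sequence=False),
    )
    head = (DenseBlockSpec(n_units=2, activation="softmax"),)
    return ArchitectureSpec(
        name="erisnet", input_layout=layout,
        conv_blocks=conv, recurrent_blocks=recurrent, dense_blocks=head,
    )


def mlp_spec() -> ArchitectureSpec:
    """Multilayer perceptron baseline: 14 → 500 → 500 → 500 → 2.

    Hidden layers use ReLU with dropout (0.2, 0.2, 0.3); the head is a
    2-way softmax.  Exactly 509,502 trainable parameters.
    """
    hidden = tuple(
        DenseBlockSpec(n_units=500, activation="relu", dropout_rate=rate)
        for rate in (0.2, 0.2, 0.3)
    )
    head = (DenseBlockSpec(n_units=2, activation="softmax"),)
    return ArchitectureSpec(
        name="mlp", input_layout=(14, 1), dense_blocks=hidden + head,
    )


def fcn_spec(input_layout=(14, 1)) -> ArchitectureSpec:
    """Fully convolutional baseline: (128,8), (256,5), (128,3) blocks in
    conv → BN → ReLU order, global average pooling, softmax head."""
    layout = _check_layout(input_layout)
    conv = tuple(
        ConvBlockSpec(
            n_filters=f, kernel_size=k, activation="relu", batch_norm=True,
            dropout_rate=0.0, l2_coefficient=0.0, order="conv_bn_relu",
        )
        for f, k in ((128, 8), (256, 5), (128, 3))
    )
    head = (DenseBlockSpec(n_units=2, activation="softmax"),)
    return ArchitectureSpec(
        name="fcn", input_layout=layout, conv_blocks=conv,
        dense_blocks=head, global_average_pool=True,
    )


def parameter_count(spec: ArchitectureSpec) -> int:
    """Trainable parameters of the built network, in closed form.

    Conv block: (C_in · k + 1) · C_out weights+biases, plus 2 · C_out
    batch-norm scale/shift when present.  LSTM block: 4 · H ·
    (C_in + H + 1), plus 2 · H for its batch norm.  Dense block:
    (fan_in + 1) · n_units.  Running batch-norm statistics are not
    trainable and are not counted.
    """
    total = 0
    length, channels = spec.input_layout
    for block in spec.conv_blocks:
        total += (channels * block.kernel_size + 1) * block.n_filters
        if block.batch_norm:
            total += 2 * block.n_filters
        channels = block.n_filters
    for block in spec.recurrent_blocks:
        total += 4 * block.n_units * (channels + block.n_units + 1)
        if block.batch_norm:
            total += 2 * block.n_units
        channels = block.n_units
    if spec.conv_blocks or spec.recurrent_blocks:
        if spec.recurrent_blocks and not spec.recurrent_blocks[-1].emits_sequence:
            fan_in = channels  # final LSTM state
        elif spec.global_average_pool:
            fan_in = channels
        else:
            fan_in = channels * length  # flattened sequence
    else:
        fan_in = length * spec.input_layout[1]
    for block in spec.dense_blocks:
        total += (fan_in + 1) * block.n_units
        fan_in = block.n_units
    return total


def describe(spec: ArchitectureSpec) -> str:
    """Human-readable block table with the trainable parameter count."""
    lines = [f"{spec.name}  (input layout {spec.input_layout[0]}x{spec.input_layout[1]})"]
    for i, b in enumerate(spec.conv_blocks, 1):
        extras = [b.order.replace("_", "->")]
        if b.dropout_rate:
            extras.append(f"dropout {b.dropout_rate}")
        if b.l2_coefficient:
            extras.append(f"L2 {b.l2_coefficient}")
        lines.append(f"  conv{i}: {b.n_filters} filters x {b.kernel_size}  ({', '.join(extras)})")
    for i, b in enumerate(spec.recurrent_blocks, 1):
        mode = "sequence" if b.emits_sequence else "final state"
        bn = ", batch norm" if b.batch_norm else ""
        lines.append(f"  lstm{i}: {b.n_units} units ({mode}{bn})")
    if spec.global_average_pool:
        lines.append("  global average pool")
    for i, b in enumerate(spec.dense_blocks, 1):
        drop = f", dropout {b.dropout_rate}" if b.dropout_rate else ""
        lines.append(f"  dense{i}: {b.n_units} units, {b.activation}{drop}")
    lines.append(f"  trainable parameters: {parameter_count(spec):,}")
    return "\n".join(lines)
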