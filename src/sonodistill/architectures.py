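"""Student and teacher network families for standard-plane classification.

Two fully convolutional families are provided:

* **SmallNet** — a six-convolution network (7x7, 5x5, 3x3, 3x3, 1x1, 1x1)
  with channel widths (C, 2C, 4C, 4C, 2C, K), biased convolutions, no batch
  normalisation, two 2x2 max pools, and a global average pool producing the
  K class logits.  SmallNet32 (C=32, K=6) has 282,950 parameters.
* **SonoNet** — a VGG-style 13-convolution feature extractor in five blocks
  of widths (C,C | 2C,2C | 4C,4C,4C | 8C,8C,8C | 8C,8C,8C), every
  convolution biased, batch-normalised and rectified, max pools between
  blocks, followed by a 1x1 adaptation convolution to 4C (BN + ReLU) and a
  1x1 convolution to K (BN), then global average pooling.  There is no
  fully connected layer anywhere.

A VGG16 classification head (13 biased convolutions, global average pool,
one dense layer) is included as the classical-CNN teacher.  "Logits" always
means the global-average-pooled pre-softmax K-vector.

Networks are fully convolutional, so the parameter count is independent of
the input resolution; the default working resolution is 224x288 (H x W)
and is freely configurable.

Every rectified convolution output is registered as a potential *feature
tap* for distillation; :func:`get_feature_taps` selects the 2-, 3- or
4-tier hand-crafted association (first / intermediate / last, optionally
plus the midpoint of the second half).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    Dense,
    GlobalAvgPool,
    Layer,
    MaxPool2d,
    ReLU,
    Sequential,
)

__all__ = [
    "ArchitectureSpec",
    "FeatureTap",
    "ParameterConvention",
    "Network",
    "ExternalTeacher",
    "build_smallnet",
    "build_sononet",
    "build_vgg16_head",
    "build_network",
    "count_parameters",
    "get_feature_taps",
    "summary",
    "REGISTRY",
]


class InvalidSpecError(ValueError):
    """Raised for architecture specs that violate family constraints."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one family member.

    ``base_width`` is the first-layer channel count C; each family expands
    it with a fixed multiple pattern.  Instantiating the same spec twice
    yields identical layer shapes and parameter counts.
    """

    family: str
    base_width: int
    num_classes: int = 6
    input_channels: int = 1

    def __post_init__(self) -> None:
        if self.family not in ("smallnet", "sononet", "vgg16_head", "external_teacher"):
            raise InvalidSpecError(f"unknown family {self.family!r}")
        if self.base_width < 1:
            raise InvalidSpecError("base_width must be >= 1")
        if self.num_classes < 2:
            raise InvalidSpecError("need at least two classes")
        if self.input_channels < 1:
            raise InvalidSpecError("input_channels must be >= 1")


@dataclass(frozen=True)
class FeatureTap:
    """One rectified-convolution output used for feature distillation.

    ``layer_index`` addresses the activation inside the network's layer
    chain; ``depth`` is the 1-based position among all rectified
    convolutions, so taps of one network are strictly ordered.
    """

    name: str  # first | intermediate | last | second_half_mid
    channels: int
    depth: int
    layer_index: int


@dataclass(frozen=True)
class ParameterConvention:
    """How parameters are counted: conv/dense weights, biases, and four
    stored entries per batch-norm channel (scale, shift, running mean,
    running variance)."""

    count_conv_weights: bool = True
    count_biases: bool = True
    batchnorm_entries_per_channel: int = 4


class Network:
    """A sequential classifier with registered feature-tap points.

    ``forward`` returns the logits (N, K); with ``tap_depths`` it also
    returns the feature maps at the requested rectified-conv depths.
    """

    def __init__(
        self,
        spec: ArchitectureSpec,
        layers: Sequence[Layer],
        rectified_convs: Sequence[tuple[int, int]],
        name: str,
    ) -> None:
        self.spec = spec
        self.seq = Sequential(layers)
        # (layer_index_of_relu_output, channels), ordered by depth
        self.rectified_convs = list(rectified_convs)
        self.name = name

    @property
    def num_classes(self) -> int:
        return self.spec.num_classes

    @property
    def input_channels(self) -> int:
        return self.spec.input_channels

    def parameters(self):
        return self.seq.parameters()

    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        tap_depths: Sequence[int] = (),
    ):
        x = np.asarray(x, dtype=float)
        if x.ndim != 4:
            raise ValueError("expected input of shape (N, C, H, W)")
        if tap_depths:
            indices = [self.rectified_convs[d - 1][0] for d in tap_depths]
            logits, taps = self.seq.forward(x, train=train, tap_indices=indices)
            return logits, {d: taps[self.rectified_convs[d - 1][0]] for d in tap_depths}
        return self.seq.forward(x, train=train)

    def backward(self, dlogits: np.ndarray, tap_grads: dict[int, np.ndarray] | None = None):
        by_index = None
        if tap_grads:
            by_index = {self.rectified_convs[d - 1][0]: g for d, g in tap_grads.items()}
        return self.seq.backward(dlogits, by_index)

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class predictions in evaluation mode."""
        out = []
        for i in range(0, len(x), batch_size):
            out.append(np.argmax(self.forward(x[i : i + batch_size]), axis=1))
        return np.concatenate(out) if out else np.zeros(0, dtype=int)

    def state(self):
        return self.seq.state()

    def load_state(self, arrays) -> None:
        self.seq.load_state(arrays)


def _conv_relu(
    layers, rect, cin, cout, k, rng, *, batchnorm=False, relu=True
):
    layers.append(Conv2d(cin, cout, k, bias=True, rng=rng))
    if batchnorm:
        layers.append(BatchNorm2d(cout))
    if relu:
        layers.append(ReLU())
        rect.append((len(layers) - 1, cout))


def build_smallnet(
    base_width: int,
    num_classes: int = 6,
    input_channels: int = 1,
    *,
    rng: np.random.Generator | None = None,
) -> Network:
    """Build a SmallNet (paper-faithful widths: 16 or 32).

    Layer schedule: conv7x7 -> C, pool, conv5x5 -> 2C, pool,
    conv3x3 -> 4C, conv3x3 -> 4C, conv1x1 -> 2C, conv1x1 -> K (not
    rectified), global average pool.  No batch normalisation.
    """
    spec = ArchitectureSpec("smallnet", base_width, num_classes, input_channels)
    rng = rng if rng is not None else np.random.default_rng(0)
    c = base_width
    layers: list[Layer] = []
    rect: list[tuple[int, int]] = []
    _conv_relu(layers, rect, input_channels, c, 7, rng)
    layers.append(MaxPool2d())
    _conv_relu(layers, rect, c, 2 * c, 5, rng)
    layers.append(MaxPool2d())
    _conv_relu(layers, rect, 2 * c, 4 * c, 3, rng)
    _conv_relu(layers, rect, 4 * c, 4 * c, 3, rng)
    _conv_relu(layers, rect, 4 * c, 2 * c, 1, rng)
    layers.append(Conv2d(2 * c, num_classes, 1, bias=True, rng=rng))  # logit map
    layers.append(GlobalAvgPool())
    return Network(spec, layers, rect, f"smallnet{base_width}")


_SONONET_BLOCKS = [(1, 2), (2, 2), (4, 3), (8, 3), (8, 3)]  # (width multiple, convs)


def build_sononet(
    base_width: int,
    num_classes: int = 6,
    input_channels: int = 1,
    *,
    rng: np.random.Generator | None = None,
) -> Network:
    """Build a SonoNet (paper-faithful widths: 8, 16, 32 or 64).

    Thirteen 3x3 convolutions (all biased, batch-normalised, rectified) in
    five max-pooled blocks, then a 1x1 adaptation convolution to 4C
    (BN + ReLU) and a 1x1 convolution to K (BN only), global average pool.
    """
    spec = ArchitectureSpec("sononet", base_width, num_classes, input_channels)
    rng = rng if rng is not None else np.random.default_rng(0)
    c = base_width
    layers: list[Layer] = []
    rect: list[tuple[int, int]] = []
    cin = input_channels
    for bi, (mult, n_convs) in enumerate(_SONONET_BLOCKS):
        for _ in range(n_convs):
            _conv_relu(layers, rect, cin, mult * c, 3, rng, batchnorm=True)
            cin = mult * c
        if bi < len(_SONONET_BLOCKS) - 1:
            layers.append(MaxPool2d())
    _conv_relu(layers, rect, cin, 4 * c, 1, rng, batchnorm=True)
    layers.append(Conv2d(4 * c, num_classes, 1, bias=True, rng=rng))
    layers.append(BatchNorm2d(num_classes))
    layers.append(GlobalAvgPool())
    return Network(spec, layers, rect, f"sononet{base_width}")


_VGG16_WIDTHS = [(64, 2), (128, 2), (256, 3), (512, 3), (512, 3)]


def build_vgg16_head(
    num_classes: int = 6, *, rng: np.random.Generator | None = None
) -> Network:
    """VGG16 feature extractor (3-channel input, biased convolutions, no
    batch norm) with a global average pool and a single 512 -> K dense
    layer."""
    spec = ArchitectureSpec("vgg16_head", 64, num_classes, 3)
    rng = rng if rng is not None else np.random.default_rng(0)
    layers: list[Layer] = []
    rect: list[tuple[int, int]] = []
    cin = 3
    for width, n_convs in _VGG16_WIDTHS:
        for _ in range(n_convs):
            _conv_relu(layers, rect, cin, width, 3, rng)
            cin = width
        layers.append(MaxPool2d())
    layers.append(GlobalAvgPool())
    layers.append(Dense(512, num_classes, rng=rng))
    return Network(spec, layers, rect, "vgg16")


def count_parameters(
    network: Network, convention: ParameterConvention = ParameterConvention()
) -> int:
    """Total stored parameters: conv/dense weights + biases + 4 entries per
    batch-norm channel.  Deterministic and independent of input size."""
    total = 0
    for layer in network.seq.layers:
        if isinstance(layer, (Conv2d, Dense)):
            if convention.count_conv_weights:
                total += layer.weight.value.size
            if convention.count_biases and layer.bias is not None:
                total += layer.bias.value.size
        elif isinstance(layer, BatchNorm2d):
            total += convention.batchnorm_entries_per_channel * layer.channels
    return total


def get_feature_taps(network: Network, n_taps: int) -> list[FeatureTap]:
    """Select the hand-crafted 2/3/4-tier tap association.

    With m rectified convolutions (1-based depths 1..m):
    n=2 -> first and last; n=3 -> first, median ((1+m)//2), last;
    n=4 -> additionally the midpoint of the second half of the model.
    Returned shallowest-first.
    """
    if n_taps not in (2, 3, 4):
        raise ValueError("tap count must be 2, 3 or 4")
    m = len(network.rectified_convs)
    if m < n_taps:
        raise ValueError(f"network has only {m} rectified convolutions")
    first, last = 1, m
    median = (1 + m) // 2
    depths = {2: [first, last], 3: [first, median, last]}.get(n_taps)
    names = {2: ["first", "last"], 3: ["first", "intermediate", "last"]}.get(n_taps)
    if n_taps == 4:
        half_mid = (median + 1 + m) // 2  # midpoint of the second half (median, m]
        depths = [first, median, half_mid, last]
        names = ["first", "intermediate", "second_half_mid", "last"]
    taps = []
    for name, d in zip(names, depths):
        layer_index, channels = network.rectified_convs[d - 1]
        taps.append(FeatureTap(name=name, channels=channels, depth=d, layer_index=layer_index))
    return taps


class ExternalTeacher:
    """Thin adapter for teacher models built outside this package.

    Any object can serve as a distillation teacher if it exposes logits
    and ordered rectified-convolution feature maps.  Wrap it in this
    adapter by supplying ``forward_fn(x, tap_depths) -> (logits, {depth:
    map})`` plus the per-depth channel counts; the training loop then
    treats it exactly like a native :class:`Network` (evaluation mode,
    no gradients).
    """

    def __init__(
        self,
        forward_fn,
        rectified_channels: Sequence[int],
        num_classes: int,
        input_channels: int = 3,
        name: str = "external",
    ) -> None:
        self._forward_fn = forward_fn
        self.rectified_convs = [(i, c) for i, c in enumerate(rectified_channels)]
        self.spec = ArchitectureSpec("external_teacher", max(rectified_channels), num_classes, input_channels)
        self.name = name

    @property
    def num_classes(self) -> int:
        return self.spec.num_classes

    @property
    def input_channels(self) -> int:
        return self.spec.input_channels

    def forward(self, x, train: bool = False, tap_depths: Sequence[int] = ()):
        if train:
            raise RuntimeError("external teachers are inference-only")
        return self._forward_fn(np.asarray(x, dtype=float), tuple(tap_depths))


def _registry() -> dict[str, Callable[..., Network]]:
    reg: dict[str, Callable[..., Network]] = {}
    for w in (16, 32):
        reg[f"smallnet{w}"] = (
            lambda num_classes=6, rng=None, _w=w: build_smallnet(_w, num_classes, 1, rng=rng)
        )
    for w in (8, 16, 32, 64):
        reg[f"sononet{w}"] = (
            lambda num_classes=6, rng=None, _w=w: build_sononet(_w, num_classes, 1, rng=rng)
        )
    reg["vgg16"] = lambda num_classes=6, rng=None: build_vgg16_head(num_classes, rng=rng)
    return reg


REGISTRY = _registry()


def build_network(name: str, num_classes: int = 6, rng: np.random.Generator | None = None) -> Network:
    """Instantiate a registered architecture by name (e.g. ``smallnet32``).

    Non-registry widths (useful for small experiments) are accepted as
    ``smallnetN`` / ``sononetN`` for any positive integer N.
    """
    if name in REGISTRY:
        return REGISTRY[name](num_classes=num_classes, rng=rng)
    for family, builder in (("smallnet", build_smallnet), ("sononet", build_sononet)):
        if name.startswith(family):
            try:
                width = int(name[len(family) :])
            except ValueError:
                break
            return builder(width, num_classes, 1, rng=rng)
    raise KeyError(f"unknown architecture {name!r}; registered: {sorted(REGISTRY)}")


def summary(network: Network) -> str:
    """A layer table with per-layer parameter counts and the total."""
    lines = [f"{network.name}  (K={network.num_classes}, in={network.input_channels}ch)"]
    lines.append(f"{'#':>3} {'layer':<22} {'params':>10}")
    total = 0
    for i, layer in enumerate(network.seq.layers):
        if isinstance(layer, Conv2d):
            n = layer.weight.value.size + (layer.bias.value.size if layer.bias else 0)
            desc = (
                f"conv {layer.kernel_size}x{layer.kernel_size} "
                f"{layer.in_channels}->{layer.out_channels}"
            )
        elif isinstance(layer, Dense):
            n = layer.weight.value.size + layer.bias.value.size
            desc = f"dense {layer.weight.value.shape[1]}->{layer.weight.value.shape[0]}"
        elif isinstance(layer, BatchNorm2d):
            n = 4 * layer.channels
            desc = f"batchnorm {layer.channels}"
        else:
            n = 0
            desc = type(layer).__name__.lower()
        total += n
        lines.append(f"{i:>3} {desc:<22} {n:>10,}")
    lines.append(f"{'':>3} {'total':<22} {total:>10,}")
    return "\n".join(lines)
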