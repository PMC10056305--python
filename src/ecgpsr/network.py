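"""CNN architecture descriptions, shape propagation and parameter counting.

Two architectures are built in: an AlexNet-derived network for 256 x 256
portrait images (five conv layers, three FC layers) and a scaled-down
network for 32 x 32 images (two conv layers, three FC layers).  Both end
in a softmax output layer with one node per enrolled individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

LAYER_KINDS = ("conv2d", "maxpool2d", "flatten", "fully_connected", "dropout")


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    in_channels: int | None = None
    out_channels: int | None = None
    kernel: int | None = None
    padding: int = 0
    stride: int = 1
    keep_prob: float | None = None
    activation: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv2d", "maxpool2d"):
            if self.kernel is None or self.kernel < 1:
                raise ValueError("kernel must be >= 1")
            if self.stride < 1 or self.padding < 0:
                raise ValueError("stride must be >= 1 and padding >= 0")
        if self.kind == "dropout":
            if self.keep_prob is None or not 0 < self.keep_prob < 1:
                raise ValueError("dropout keep probability must lie in (0, 1)")


@dataclass(frozen=True)
class NetworkSpec:
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int]  # height, width, channels
    num_classes: int

    def to_dict(self) -> dict:
        return {"input_shape": list(self.input_shape),
                "num_classes": self.num_classes,
                "layers": [asdict(l) for l in self.layers]}

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(layers=tuple(LayerSpec(**l) for l in d["layers"]),
                   input_shape=tuple(d["input_shape"]),
                   num_classes=int(d["num_classes"]))


def conv_output_size(n: int, k: int, p: int, s: int) -> int:
    """Spatial output extent of a convolution/pool: floor((n + 2p - k)/s) + 1."""
    if s < 1:
        raise ValueError("stride must be >= 1")
    if k > n + 2 * p:
        raise ValueError(f"kernel {k} exceeds padded extent {n + 2 * p}")
    return (n + 2 * p - k) // s + 1


def propagate_shapes(spec: NetworkSpec) -> list[tuple]:
    """Output shape after every layer; (h, w, c) before flatten, (n,) after.

    Raises if any intermediate dimension becomes non-positive, naming the
    offending layer.
    """
    shapes: list[tuple] = []
    shape: tuple = spec.input_shape
    for i, layer in enumerate(spec.layers):
        if layer.kind in ("conv2d", "maxpool2d"):
            h, w, c = shape
            if layer.kind == "conv2d" and c != layer.in_channels:
                raise ValueError(
                    f"layer {i} ({layer.kind}): expects {layer.in_channels} "
                    f"channels, got {c}")
            try:
                h = conv_output_size(h, layer.kernel, layer.padding,
                                     layer.stride)
                w = conv_output_size(w, layer.kernel, layer.padding,
                                     layer.stride)
            except ValueError as err:
                raise ValueError(f"layer {i} ({layer.kind}): {err}") from None
            shape = (h, w, layer.out_channels if layer.kind == "conv2d" else c)
        elif layer.kind == "flatten":
            h, w, c = shape
            shape = (h * w * c,)
        elif layer.kind == "fully_connected":
            (n,) = shape
            if n != layer.in_channels:
                raise ValueError(
                    f"layer {i} (fully_connected): expects {layer.in_channels} "
                    f"inputs, got {n}")
            shape = (layer.out_channels,)
        elif layer.kind == "dropout":
            pass
        if any(d <= 0 for d in shape):
            raise ValueError(f"layer {i} ({layer.kind}): non-positive "
                             f"dimension in shape {shape}")
        shapes.append(shape)
    return shapes


def count_parameters(spec: NetworkSpec) -> int:
    """Trainable parameter count: conv k^2*in*out + out; fc in*out + out."""
    propagate_shapes(spec)
    total = 0
    for layer in spec.layers:
        if layer.kind == "conv2d":
            total += layer.kernel**2 * layer.in_channels * layer.out_channels
            total += layer.out_channels
        elif layer.kind == "fully_connected":
            total += layer.in_channels * layer.out_channels + layer.out_channels
    return total


def build_original_spec(num_classes: int) -> NetworkSpec:
    """AlexNet-derived architecture for 256 x 256 x 1 portrait images.

    Five conv layers with interleaved max pooling, then FC 12544-4096-4096
    with dropout 0.5 and a softmax output layer.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    conv = lambda ci, co, k, p=0, s=1: LayerSpec(
        "conv2d", in_channels=ci, out_channels=co, kernel=k, padding=p,
        stride=s, activation="relu")
    pool = lambda k, s: LayerSpec("maxpool2d", kernel=k, stride=s)
    fc = lambda i, o, act: LayerSpec("fully_connected", in_channels=i,
                                     out_channels=o, activation=act)
    drop = LayerSpec("dropout", keep_prob=0.5)
    layers = (
        conv(1, 96, 12, 0, 4),
        pool(2, 2),
        conv(96, 256, 5, 2, 1),
        pool(3, 2),
        conv(256, 384, 3, 1, 1),
        conv(384, 384, 3, 1, 1),
        conv(384, 256, 3, 1, 1),
        pool(3, 2),
        LayerSpec("flatten"),
        fc(12544, 4096, "relu"), drop,
        fc(4096, 4096, "relu"), drop,
        fc(4096, num_classes, "softmax"),
    )
    return NetworkSpec(layers=layers, input_shape=(256, 256, 1),
                       num_classes=num_classes)


def build_scaled_spec(num_classes: int) -> NetworkSpec:
    """Scaled-down architecture for 32 x 32 x 1 portrait images."""
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    layers = (
        LayerSpec("conv2d", in_channels=1, out_channels=32, kernel=5,
                  activation="relu"),
        LayerSpec("maxpool2d", kernel=2, stride=2),
        LayerSpec("conv2d", in_channels=32, out_channels=32, kernel=2,
                  activation="relu"),
        LayerSpec("flatten"),
        LayerSpec("fully_connected", in_channels=5408, out_channels=1024,
                  activation="relu"),
        LayerSpec("dropout", keep_prob=0.5),
        LayerSpec("fully_connected", in_channels=1024, out_channels=1024,
                  activation="relu"),
        LayerSpec("dropout", keep_prob=0.5),
        LayerSpec("fully_connected", in_channels=1024,
                  out_channels=num_classes, activation="softmax"),
    )
    return NetworkSpec(layers=layers, input_shape=(32, 32, 1),
                       num_classes=num_classes)


def describe(spec: NetworkSpec) -> str:
    """Human-readable shape table with the total parameter count."""
    shapes = propagate_shapes(spec)
    lines = [f"{'layer':<16}{'output shape':<20}"]
    for layer, shape in zip(spec.layers, shapes):
        lines.append(f"{layer.kind:<16}{str(shape):<20}")
    lines.append(f"total parameters: {count_parameters(spec):,}")
    return "\n".join(lines)
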