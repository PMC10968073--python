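"""CNN architecture specifications and dimension propagation.

Three detectors share one spec language:

* **WS-CNN** -- 17 layers: 7 conv blocks (batch-norm + ReLU; filters
  32, 48, 64, 96, 128, 192, 256; kernel 3, stride 1, pad 1) alternating with
  7 max-pools (kernels [3,2], 2, 3, [3,2], [2,3], [4,5], 2; stride 2, pad 0)
  over a 333x500x3 scalogram image, then flatten (1536) -> dense 24 ->
  dense 2 -> softmax.
* **WF-CNN** -- 14 layers over the L x 3 x 1 feature matrix: 6 conv blocks
  with 5 interleaved time-axis pools (kernel [4,1], stride [4,1]; never more
  than a 4x reduction per pool, preserving the 3-column axis throughout),
  then flatten -> dense 24 -> dense 2 -> softmax.
* **1D-CNN** -- 14 layers over the raw L x 1 x 1 segment, same schedule as
  the WF net with 1-wide kernels.

Spatial sizes follow the floor rule ``out = (in + 2*pad - k)//stride + 1``;
propagation raises, naming the offending layer, whenever a dimension would
collapse to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# canonical input geometries
WS_INPUT_SHAPE = (333, 500, 3)  # scalogram image H x W x C
WS_FILTERS = (32, 48, 64, 96, 128, 192, 256)
WS_POOLS = ((3, 2), (2, 2), (3, 3), (3, 2), (2, 3), (4, 5), (2, 2))

WF_FILTERS = (32, 32, 48, 48, 64, 64)
ONED_FILTERS = (16, 32, 48, 64, 96, 128)


class PropagationError(ValueError):
    """A layer's output would have a non-positive spatial size."""


@dataclass
class Layer:
    """One layer descriptor.

    kind: conv | max_pool | flatten | fully_connected | softmax
    kernel/stride/padding are (h, w) pairs for conv and max_pool.
    """

    kind: str
    kernel: tuple[int, int] | None = None
    stride: tuple[int, int] | None = None
    padding: tuple[int, int] | None = None
    filters: int | None = None
    units: int | None = None
    batch_norm: bool = False
    relu: bool = False


@dataclass
class CnnSpec:
    """An ordered stack of layer descriptors plus the input geometry."""

    name: str
    input_shape: tuple[int, int, int]  # H, W, C
    layers: list[Layer] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        """Depth by the counting convention used for the detector names:
        conv + pool + flatten + dense layers (softmax head uncounted)."""
        return sum(1 for l in self.layers if l.kind != "softmax")

    def propagate(self) -> list[tuple]:
        """Output shape after every layer; raises PropagationError early.

        Conv/pool shapes are (H, W, C); flatten and dense shapes are (n,).
        """
        h, w, c = self.input_shape
        shapes: list[tuple] = []
        for i, layer in enumerate(self.layers):
            if layer.kind == "conv":
                kh, kw = layer.kernel
                sh, sw = layer.stride
                ph, pw = layer.padding
                h = (h + 2 * ph - kh) // sh + 1
                w = (w + 2 * pw - kw) // sw + 1
                c = layer.filters
            elif layer.kind == "max_pool":
                kh, kw = layer.kernel
                sh, sw = layer.stride
                h = (h - kh) // sh + 1
                w = (w - kw) // sw + 1
            elif layer.kind == "flatten":
                shapes.append((h * w * c,))
                h = None
                continue
            elif layer.kind == "fully_connected":
                shapes.append((layer.units,))
                continue
            elif layer.kind == "softmax":
                shapes.append(shapes[-1])
                continue
            else:
                raise ValueError(f"unknown layer kind {layer.kind!r}")
            if h < 1 or w < 1:
                raise PropagationError(
                    f"{self.name}: layer {i} ({layer.kind}) collapses the "
                    f"spatial size to {h}x{w}"
                )
            shapes.append((h, w, c))
        return shapes

    @property
    def flatten_width(self) -> int:
        """Feature count entering the first dense layer."""
        for layer, shape in zip(self.layers, self.propagate()):
            if layer.kind == "flatten":
                return shape[0]
        raise ValueError("spec has no flatten layer")


def _conv_pool_stack(
    name: str,
    input_shape: tuple[int, int, int],
    filters: tuple[int, ...],
    pools: tuple[tuple[int, int] | None, ...],
    conv_kernel: tuple[int, int] = (3, 3),
    conv_padding: tuple[int, int] = (1, 1),
    dense_units: int = 24,
) -> CnnSpec:
    layers: list[Layer] = []
    for f, pool in zip(filters, pools):
        layers.append(
            Layer(
                kind="conv",
                kernel=conv_kernel,
                stride=(1, 1),
                padding=conv_padding,
                filters=f,
                batch_norm=True,
                relu=True,
            )
        )
        if pool is not None:
            layers.append(
                Layer(kind="max_pool", kernel=pool, stride=(2, 2), padding=(0, 0))
            )
    layers.append(Layer(kind="flatten"))
    layers.append(Layer(kind="fully_connected", units=dense_units, relu=True))
    layers.append(Layer(kind="fully_connected", units=2))
    layers.append(Layer(kind="softmax"))
    spec = CnnSpec(name=name, input_shape=input_shape, layers=layers)
    spec.propagate()  # fail fast on an incompatible input shape
    return spec


def build_ws_cnn(
    input_shape: tuple[int, int, int] = WS_INPUT_SHAPE,
    filters: tuple[int, ...] = WS_FILTERS,
    pools: tuple[tuple[int, int], ...] = WS_POOLS,
) -> CnnSpec:
    """The 17-layer scalogram-image classifier.

    Defaults reproduce the reference schedule exactly: propagation from
    333x500 gives 166x250, 83x125, 41x62, 20x31, 10x15, 4x6, 2x3 after the
    pools, and a 2*3*256 = 1536-wide flatten.
    """
    return _conv_pool_stack("ws_cnn", input_shape, filters, pools)


def build_ws_cnn_desk(
    input_shape: tuple[int, int, int] = (48, 64, 3),
    filters: tuple[int, ...] = (8, 16, 24, 32),
) -> CnnSpec:
    """Desk-scale scalogram net: same design, shrunk raster/filters/depth."""
    pools = tuple((2, 2) for _ in filters)
    return _conv_pool_stack("ws_cnn_desk", input_shape, filters, pools)


def _time_axis_spec(
    name: str,
    L: int,
    width: int,
    channels: int,
    filters: tuple[int, ...],
    kernel_w: int,
) -> CnnSpec:
    """Shared 14-layer schedule for the WF and 1-D nets.

    6 conv blocks, time-axis pools (kernel 4, stride 4 -- at most a 4x
    reduction each) after the first 5, flatten, dense 24, dense 2.
    6 + 5 + 1 + 2 = 14 layers.
    """
    pools: tuple[tuple[int, int] | None, ...] = tuple(
        (4, 1) if i < len(filters) - 1 else None for i in range(len(filters))
    )
    layers: list[Layer] = []
    for f, pool in zip(filters, pools):
        layers.append(
            Layer(
                kind="conv",
                kernel=(5, kernel_w),
                stride=(1, 1),
                padding=(2, 0 if kernel_w == 1 else kernel_w // 2),
                filters=f,
                batch_norm=True,
                relu=True,
            )
        )
        if pool is not None:
            layers.append(
                Layer(kind="max_pool", kernel=pool, stride=(4, 1), padding=(0, 0))
            )
    layers.append(Layer(kind="flatten"))
    layers.append(Layer(kind="fully_connected", units=24, relu=True))
    layers.append(Layer(kind="fully_connected", units=2))
    layers.append(Layer(kind="softmax"))
    spec = CnnSpec(name=name, input_shape=(L, width, channels), layers=layers)
    spec.propagate()
    return spec


def build_wf_cnn(L: int = 51_302, filters: tuple[int, ...] = WF_FILTERS) -> CnnSpec:
    """The 14-layer wavelet-Fourier matrix classifier (input L x 3 x 1).

    Pooling acts only along the time axis so the 3-column feature axis is
    preserved until the dense head.
    """
    return _time_axis_spec("wf_cnn", L, width=3, channels=1, filters=filters, kernel_w=3)


def build_1d_cnn(L: int = 51_302, filters: tuple[int, ...] = ONED_FILTERS) -> CnnSpec:
    """The 14-layer raw-signal classifier (input L x 1 x 1)."""
    return _time_axis_spec("oned_cnn", L, width=1, channels=1, filters=filters, kernel_w=1)
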