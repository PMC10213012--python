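"""Generator and discriminator architectures.

Generators are resnet encoder/decoder translators (stride-2 encoder,
residual blocks, mirrored decoder); the hierarchical variant pairs a
global low-resolution generator G1 with a local high-resolution enhancer
G2 whose features are fused with G1's backbone features, coarse-to-fine.
Discriminators are fully-convolutional patch classifiers ("PatchGAN");
their patch size is the receptive field of one output unit, which for the
4x4-kernel, four-stride-2-layer configuration is 142 x 142 pixels.

Images enter and leave on the normalized [0, 255] scale; generators scale
internally to [-1, 1] and bound their output with a tanh.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, avgpool2x, upsample2x
from .nn import (
    Conv2d,
    InstanceNorm2d,
    LeakyReLU,
    Module,
    ReLU,
    ResidualBlock,
    Sequential,
    Sigmoid,
)

__all__ = [
    "GeneratorSpec",
    "DiscriminatorSpec",
    "receptive_field",
    "build_generator",
    "build_hierarchical_generator",
    "build_discriminator",
    "gradient_support_size",
    "ResnetGenerator",
    "HierarchicalGenerator",
    "PatchDiscriminator",
]


def receptive_field(kernel: int, stride2_layers: int, stride1_layers: int) -> int:
    """Receptive field of a stack of stride-2 then stride-1 convolutions.

    Standard recurrence: starting from r = 1, j = 1, each layer grows the
    field by (k - 1) * j and multiplies the jump j by its stride.  The
    final 1-channel output convolution counts as one of the stride-1
    layers.
    """
    if kernel < 1 or stride2_layers < 0 or stride1_layers < 0:
        raise ValueError("kernel >= 1 and layer counts >= 0 required")
    r, j = 1, 1
    for _ in range(stride2_layers):
        r += (kernel - 1) * j
        j *= 2
    for _ in range(stride1_layers):
        r += (kernel - 1) * j
    return r


@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture of one translator direction.

    ``in_channels``/``out_channels`` are 1 and K+1 for the decomposing
    generator and K+1 and 1 for the reverse generator.
    """

    in_channels: int
    out_channels: int
    residual_blocks: int = 9
    downsample_layers: int = 4  # 4 conventional, 3 proposed
    base_width: int = 64
    hierarchical: bool = False
    scales: tuple[int, int] = (256, 512)  # (low, high) when hierarchical
    enhancer_blocks: int = 3
    max_width_factor: int = 4

    def __post_init__(self):
        if self.residual_blocks < 1:
            raise ValueError("residual_blocks must be >= 1")
        if not 2 <= self.downsample_layers <= 5:
            raise ValueError("downsample_layers must be in 2..5")
        if min(self.in_channels, self.out_channels, self.base_width) < 1:
            raise ValueError("channel counts and base_width must be >= 1")
        if self.hierarchical and self.scales[1] != 2 * self.scales[0]:
            raise ValueError("hierarchical scales must satisfy high = 2 * low")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Patch-discriminator architecture (4x4 kernels)."""

    in_channels: int
    stride2_layers: int = 4  # 4 conventional, 3 proposed
    kernel: int = 4
    base_width: int = 64
    max_width_factor: int = 8

    def __post_init__(self):
        if self.stride2_layers < 1:
            raise ValueError("stride2_layers must be >= 1")
        if self.kernel < 1:
            raise ValueError("kernel must be >= 1")

    @property
    def receptive_field(self) -> int:
        # stride-2 stack, then the stride-1 conv and the stride-1 output conv
        return receptive_field(self.kernel, self.stride2_layers, 2)


def _widths(base: int, n: int, cap: int) -> list[int]:
    return [min(base * 2**i, base * cap) for i in range(n + 1)]


class ResnetGenerator(Module):
    """Encoder / residual-blocks / decoder image translator."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        w = _widths(spec.base_width, spec.downsample_layers, spec.max_width_factor)
        stem = [
            Conv2d(spec.in_channels, w[0], 7, pad_mode="reflect", rng=rng),
            InstanceNorm2d(w[0]),
            ReLU(),
        ]
        down = []
        for i in range(spec.downsample_layers):
            down += [
                Conv2d(w[i], w[i + 1], 3, stride=2, rng=rng),
                InstanceNorm2d(w[i + 1]),
                ReLU(),
            ]
        blocks = [ResidualBlock(w[-1], rng=rng) for _ in range(spec.residual_blocks)]
        up = []
        for i in range(spec.downsample_layers, 0, -1):
            up += [
                _UpsampleConv(w[i], w[i - 1], rng=rng),
                InstanceNorm2d(w[i - 1]),
                ReLU(),
            ]
        self.backbone = Sequential(*stem, *down, *blocks, *up)
        self.head = Conv2d(w[0], spec.out_channels, 7, pad_mode="reflect", rng=rng)
        self.feature_width = w[0]

    def forward(self, x: Tensor, return_features: bool = False):
        h = self.backbone(x * (1.0 / 127.5) - 1.0)
        out = (self.head(h).tanh() + 1.0) * 127.5
        return (out, h) if return_features else out


class _UpsampleConv(Module):
    """Nearest-neighbour upsample followed by a 3x3 convolution."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(upsample2x(x))


class _LocalEnhancer(Module):
    """High-resolution correction branch of the hierarchical generator.

    Front end downsamples the high-resolution input to the low scale,
    where its features are fused (by addition) with the upsampled global
    generator's backbone features; residual blocks and an upsampling tail
    then produce an image-space correction whose final convolution is
    zero-initialized, so the composed generator starts as the upsampled
    global generator exactly.
    """

    def __init__(self, spec: GeneratorSpec, feature_width: int,
                 rng: np.random.Generator):
        super().__init__()
        w = max(feature_width // 2, 1)
        self.stem = Sequential(
            Conv2d(spec.in_channels, w, 7, pad_mode="reflect", rng=rng),
            InstanceNorm2d(w),
            ReLU(),
        )
        self.down = Sequential(
            Conv2d(w, feature_width, 3, stride=2, rng=rng),
            InstanceNorm2d(feature_width),
            ReLU(),
        )
        self.blocks = Sequential(
            *[ResidualBlock(feature_width, rng=rng)
              for _ in range(spec.enhancer_blocks)]
        )
        self.up = Sequential(
            _UpsampleConv(feature_width, w, rng=rng),
            InstanceNorm2d(w),
            ReLU(),
        )
        self.head = Conv2d(w, spec.out_channels, 7, pad_mode="reflect",
                           rng=rng, zero_init=True)

    def forward(self, x_high: Tensor, g1_features: Tensor) -> Tensor:
        h = self.down(self.stem(x_high * (1.0 / 127.5) - 1.0))
        h = h + g1_features
        return self.head(self.up(self.blocks(h)))


class HierarchicalGenerator(Module):
    """Composed coarse-to-fine generator: upsampled G1 output + G2 correction."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        if not spec.hierarchical:
            raise ValueError("spec.hierarchical must be set")
        self.spec = spec
        self.global_net = ResnetGenerator(spec, rng)
        self.enhancer = _LocalEnhancer(spec, self.global_net.feature_width, rng)

    def forward(self, x_high: Tensor) -> Tensor:
        x_low = avgpool2x(x_high)
        g1_img, g1_feat = self.global_net(x_low, return_features=True)
        delta = self.enhancer(x_high, g1_feat)
        return upsample2x(g1_img) + delta


class PatchDiscriminator(Module):
    """Fully-convolutional patch classifier with sigmoid score map."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        k = spec.kernel
        w = _widths(spec.base_width, spec.stride2_layers, spec.max_width_factor)
        layers: list[Module] = [
            Conv2d(spec.in_channels, w[0], k, stride=2, padding=1, rng=rng),
            LeakyReLU(0.2),
        ]
        for i in range(1, spec.stride2_layers):
            layers += [
                Conv2d(w[i - 1], w[i], k, stride=2, padding=1, rng=rng),
                InstanceNorm2d(w[i]),
                LeakyReLU(0.2),
            ]
        wlast = w[spec.stride2_layers - 1]
        wpen = min(wlast * 2, spec.base_width * spec.max_width_factor)
        layers += [
            Conv2d(wlast, wpen, k, stride=1, padding=1, rng=rng),
            InstanceNorm2d(wpen),
            LeakyReLU(0.2),
            Conv2d(wpen, 1, k, stride=1, padding=1, rng=rng),
            Sigmoid(),
        ]
        self.net = Sequential(*layers)

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x * (1.0 / 127.5) - 1.0)


def build_generator(spec: GeneratorSpec, seed: int = 0) -> ResnetGenerator:
    """Build a (non-hierarchical) generator with seeded initialization."""
    return ResnetGenerator(spec, np.random.default_rng(seed))


def build_hierarchical_generator(
    spec: GeneratorSpec, seed: int = 0
) -> tuple[ResnetGenerator, _LocalEnhancer, HierarchicalGenerator]:
    """Build the (global G1, local G2, composed G) triple."""
    composed = HierarchicalGenerator(spec, np.random.default_rng(seed))
    return composed.global_net, composed.enhancer, composed


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    return PatchDiscriminator(spec, np.random.default_rng(seed))


def gradient_support_size(disc: PatchDiscriminator, input_size: int | None = None) -> int:
    """Measure the receptive field by gradient support.

    Backpropagates from one central output unit of the discriminator on a
    large enough input and returns the largest spatial extent of the
    nonzero input-gradient region.  Instance normalization couples all
    pixels through the batch statistics, so the measurement runs with the
    network's normalization layers bypassed (pure convolution stack), which
    is the quantity the receptive-field arithmetic describes.
    """
    rf = disc.spec.receptive_field
    n = input_size or int(2 ** np.ceil(np.log2(rf * 2)))
    x = Tensor(np.zeros((1, disc.spec.in_channels, n, n)), requires_grad=True)
    h = x
    for layer in disc.net.layers:
        if isinstance(layer, InstanceNorm2d):
            continue  # global statistics would make every pixel influential
        if isinstance(layer, Sigmoid):
            continue  # monotone pointwise map; keep pre-activation scores
        h = layer(h)
    _, _, ho, wo = h.shape
    seed_grad = np.zeros(h.shape)
    seed_grad[0, 0, ho // 2, wo // 2] = 1.0
    h.backward(seed_grad)
    nz = np.nonzero(np.abs(x.grad[0]).sum(axis=0) > 0)
    if len(nz[0]) == 0:
        return 0
    return int(
        max(nz[0].max() - nz[0].min() + 1, nz[1].max() - nz[1].min() + 1)
    )
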