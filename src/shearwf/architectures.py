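"""Semantic-edge-detection architectures and their complexity accounting.

Builds the computation graphs of four category-aware edge detectors on a
101-layer residual backbone: the classical architecture with a buffer
fourth stage (``casenet``), its shearlet-input variant without the fourth
stage (``shear_casenet``), the deep-diverse-supervision variant with
information converters (``dds``) and its shearlet counterpart
(``shear_dds``).  Shearlet variants take the L coefficient slices as input
channels; non-shearlet variants take RGB images.

Two parameter-count conventions are exposed.  ``weights`` counts every
trainable array of the constructed graph (convolution kernels, biases,
batch-norm affine parameters).  ``published`` reproduces the published
accounting: convolution kernel weights only for the backbone (bias-free,
batch-norm parameters not counted) plus the biased side/fusion 1x1
convolutions, with the shearlet variants counted as the non-shearlet
total minus (128 - L) * N^2 for an N x N input.  Under that accounting the
difference between a variant and its shearlet counterpart is exactly
(128 - L) * N^2 for every N and L.

The first shearlet layer can be folded into the trainable kernels by
associativity of convolution, so an L-slice system replaces 128 - L
trainable kernels by L fixed ones: 128 - 2L fewer kernels to store
whenever L < 128 - L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError, ShapeError
from .shearlets import ShearletSystem, shearlet_transform, CoefficientVolume

__all__ = [
    "ArchitectureSpec",
    "Layer",
    "Network",
    "build_network",
    "count_parameters",
    "forward_shape_pass",
    "apply_composed",
    "apply_two_path",
    "first_layer_factorization",
    "stored_kernel_reduction",
]

VARIANTS = ("casenet", "shear_casenet", "dds", "shear_dds")

# ResNet-101 stage plan: (n_blocks, mid_channels, out_channels, stride)
_STAGES = {
    "res2": (3, 64, 256, 1),
    "res3": (4, 128, 512, 2),
    "res4": (23, 256, 1024, 2),
    "res5": (3, 512, 2048, 2),
}


@dataclass(frozen=True)
class ArchitectureSpec:
    variant: str
    n_categories: int = 20
    input_size: int = 256
    shearlet_slices: int = 49  # L; used by shear variants
    input_channels: int | None = None  # default: 3 (RGB) or L
    include_stage4: bool | None = None  # default: True unless a shear variant

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InvalidConfigError(f"unknown variant {self.variant!r}")
        if self.input_channels is None:
            cin = self.shearlet_slices if self.is_shear else 3
            object.__setattr__(self, "input_channels", cin)
        if self.include_stage4 is None:
            object.__setattr__(self, "include_stage4", not self.is_shear)

    @property
    def is_shear(self) -> bool:
        return self.variant.startswith("shear_")

    @property
    def is_dds(self) -> bool:
        return self.variant.endswith("dds")

    @property
    def base_variant(self) -> str:
        return self.variant.removeprefix("shear_")


@dataclass
class Layer:
    name: str
    kind: str  # conv | bn
    cin: int = 0
    cout: int = 0
    kernel: int = 1
    stride: int = 1
    bias: bool = False
    stage: str = ""
    in_published_count: bool = True

    @property
    def n_weights(self) -> int:
        if self.kind == "bn":
            return 2 * self.cout
        n = self.cin * self.cout * self.kernel * self.kernel
        return n + (self.cout if self.bias else 0)

    @property
    def n_published(self) -> int:
        if self.kind == "bn" or not self.in_published_count:
            return 0
        n = self.cin * self.cout * self.kernel * self.kernel
        return n + (self.cout if self.bias else 0)


@dataclass
class Network:
    spec: ArchitectureSpec
    layers: list[Layer] = field(default_factory=list)

    def stage_names(self) -> set[str]:
        return {layer.stage for layer in self.layers}

    def has_stage(self, stage: str) -> bool:
        return any(layer.stage == stage for layer in self.layers)

    @property
    def first_conv(self) -> Layer:
        return next(l for l in self.layers if l.kind == "conv")


def _add_conv(net, name, cin, cout, kernel, stride=1, bias=False, stage="", bn=True):
    net.layers.append(Layer(name, "conv", cin, cout, kernel, stride, bias, stage))
    if bn:
        net.layers.append(Layer(name + ".bn", "bn", cout, cout, stage=stage))


def _add_bottleneck(net, name, cin, mid, cout, stride, stage):
    _add_conv(net, f"{name}.conv1", cin, mid, 1, stride, stage=stage)
    _add_conv(net, f"{name}.conv2", mid, mid, 3, 1, stage=stage)
    _add_conv(net, f"{name}.conv3", mid, cout, 1, 1, stage=stage)
    if cin != cout or stride != 1:
        _add_conv(net, f"{name}.downsample", cin, cout, 1, stride, stage=stage)


def build_network(spec: ArchitectureSpec) -> Network:
    """Construct the layer graph of one variant (untrained)."""
    net = Network(spec=spec)
    K = spec.n_categories
    _add_conv(net, "conv1", spec.input_channels, 64, 7, 2, stage="conv1")
    cin = 64
    for stage, (n_blocks, mid, cout, stride) in _STAGES.items():
        if stage == "res4" and not spec.include_stage4:
            continue
        for i in range(n_blocks):
            _add_bottleneck(net, f"{stage}.block{i}", cin if i == 0 else cout, mid, cout,
                            stride if i == 0 else 1, stage)
        cin = cout

    # side feature maps (category-agnostic edges) and class activation map
    _add_conv(net, "side1", 64, 1, 1, bias=True, stage="side", bn=False)
    _add_conv(net, "side2", 256, 1, 1, bias=True, stage="side", bn=False)
    _add_conv(net, "side3", 512, 1, 1, bias=True, stage="side", bn=False)
    n_sides = 3
    if spec.is_dds:
        # information converters: one residual conv block per supervised side
        side_stages = ["conv1", "res2", "res3"] + (["res4"] if spec.include_stage4 else [])
        for i, st in enumerate(side_stages, start=1):
            width = 64
            _add_conv(net, f"converter{i}.conv1", width, width, 3, stage="converter")
            _add_conv(net, f"converter{i}.conv2", width, width, 3, stage="converter")
        if spec.include_stage4:
            _add_conv(net, "side4", 1024, 1, 1, bias=True, stage="side", bn=False)
            n_sides = 4
    _add_conv(net, "class_activation", 2048, K, 1, bias=True, stage="side", bn=False)
    # K-grouped 1x1 fusion over {sides..., activation_k}
    net.layers.append(Layer("fusion", "conv", n_sides + 1, K, 1, bias=True, stage="fusion"))
    return net


def count_parameters(network: Network, input_size: int | None = None,
                     convention: str = "published") -> int:
    """Parameter total of a graph under one of the two conventions."""
    spec = network.spec
    N = input_size or spec.input_size
    if convention == "weights":
        return sum(l.n_weights for l in network.layers)
    if convention != "published":
        raise InvalidConfigError(f"unknown convention {convention!r}")
    if spec.is_shear:
        base = build_network(
            ArchitectureSpec(variant=spec.base_variant, n_categories=spec.n_categories,
                             input_size=N)
        )
        return count_parameters(base, N, "published") - (128 - spec.shearlet_slices) * N * N
    return sum(l.n_published for l in network.layers)


# ---------------------------------------------------------------------------
# Numeric forward pass (random weights, shape semantics only)


def _conv2d(x, W, stride=1):
    # x: (C, H, W); W: (O, C, k, k); "same" padding at stride 1, half at stride 2
    from numpy.lib.stride_tricks import sliding_window_view

    O, C, k, _ = W.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return np.einsum("ocij,chwij->ohw", W, win, optimize=True)


def _upsample_to(x, size):
    from scipy.ndimage import zoom

    factor = (size / x.shape[-2], size / x.shape[-1])
    return zoom(x, (1,) + factor, order=1, grid_mode=True, mode="nearest")


def forward_shape_pass(network: Network, image: np.ndarray, seed: int = 0) -> np.ndarray:
    """Run the graph with small random weights; returns the K x N x N map.

    This checks topology and shape propagation, not learned behaviour:
    weights are freshly drawn from a seeded generator, batch norm is folded
    to identity.
    """
    spec = network.spec
    N = image.shape[-1]
    if image.ndim == 2:
        image = image[None]
    if image.shape[0] != spec.input_channels:
        raise ShapeError(
            f"input has {image.shape[0]} channels, spec expects {spec.input_channels}")
    rng = np.random.default_rng(seed)

    def conv(x, cin, cout, k, stride):
        W = rng.standard_normal((cout, cin, k, k)).astype(np.float32) / np.sqrt(cin * k * k)
        return _conv2d(x, W, stride)

    x = conv(image.astype(np.float32), spec.input_channels, 64, 7, 2)
    x = np.maximum(x, 0)
    sides = [_upsample_to(conv(x, 64, 1, 1, 1), N)]
    cin = 64
    for stage, (n_blocks, mid, cout, stride) in _STAGES.items():
        if stage == "res4" and not spec.include_stage4:
            continue
        for i in range(n_blocks):
            s = stride if i == 0 else 1
            ci = cin if i == 0 else cout
            h = np.maximum(conv(x, ci, mid, 1, s), 0)
            h = np.maximum(conv(h, mid, mid, 3, 1), 0)
            h = conv(h, mid, cout, 1, 1)
            shortcut = conv(x, ci, cout, 1, s) if (ci != cout or s != 1) else x
            x = np.maximum(h + shortcut, 0)
        if stage == "res2":
            sides.append(_upsample_to(conv(x, cout, 1, 1, 1), N))
        elif stage == "res3":
            sides.append(_upsample_to(conv(x, cout, 1, 1, 1), N))
        elif stage == "res4" and spec.is_dds:
            sides.append(_upsample_to(conv(x, cout, 1, 1, 1), N))
        cin = cout
    activation = _upsample_to(conv(x, 2048, spec.n_categories, 1, 1), N)
    # shared concatenation + K-grouped 1x1 fusion
    K = spec.n_categories
    n_sides = len(sides)
    w = rng.standard_normal((K, n_sides + 1)).astype(np.float32) / np.sqrt(n_sides + 1)
    fused = np.empty((K, N, N), dtype=np.float32)
    side_stack = np.concatenate([s for s in sides], axis=0)
    for k in range(K):
        group = np.concatenate([side_stack, activation[k : k + 1]], axis=0)
        fused[k] = np.tensordot(w[k], group, axes=(0, 0))
    return fused


# ---------------------------------------------------------------------------
# First-layer factorization


def stored_kernel_reduction(n_slices: int, base_channels: int = 128) -> int:
    """Net reduction in stored convolution kernels from the shearlet layer.

    Replacing ``base_channels`` trainable first-layer kernels by L fixed
    shearlet filters composed with L trainable kernels stores base - 2L
    fewer kernels (positive whenever L < base - L).
    """
    return base_channels - 2 * n_slices


def first_layer_factorization(system: ShearletSystem, kernels: np.ndarray) -> np.ndarray:
    """Compose each shearlet filter with its trainable kernel.

    By associativity of (circular) convolution, applying the shearlet
    transform and then convolving slice l with a trainable kernel omega_l
    equals a single convolution with psi_l * omega_l.  ``kernels`` is
    (L, k, k); the result is the composed filter stack in the frequency
    domain, same layout as ``system.filters``.
    """
    L, M = system.n_slices, system.image_size
    kernels = np.asarray(kernels, dtype=float)
    if kernels.shape[0] != L:
        raise ShapeError(f"need {L} kernels, got {kernels.shape[0]}")
    k = kernels.shape[-1]
    padded = np.zeros((L, M, M))
    padded[:, :k, :k] = kernels
    # center the kernel at the origin so the composition is phase-consistent
    padded = np.roll(padded, shift=(-(k // 2), -(k // 2)), axis=(1, 2))
    khat = np.fft.fft2(padded, axes=(-2, -1))
    return np.conj(system.filters) * khat


def apply_composed(image: np.ndarray, composed: np.ndarray) -> np.ndarray:
    """Convolve an image with a composed (frequency-domain) kernel stack."""
    spectrum = np.fft.fft2(image)
    return np.fft.ifft2(spectrum[None] * composed, axes=(-2, -1)).real


def apply_two_path(image: np.ndarray, system: ShearletSystem, kernels: np.ndarray) -> np.ndarray:
    """Shearlet transform followed by per-slice circular convolution."""
    vol = shearlet_transform(image, system)
    k = kernels.shape[-1]
    M = system.image_size
    padded = np.zeros((system.n_slices, M, M))
    padded[:, :k, :k] = kernels
    padded = np.roll(padded, shift=(-(k // 2), -(k // 2)), axis=(1, 2))
    khat = np.fft.fft2(padded, axes=(-2, -1))
    return np.fft.ifft2(np.fft.fft2(vol.data, axes=(-2, -1)) * khat, axes=(-2, -1)).real
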