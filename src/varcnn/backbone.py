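"""The 3-D convolutional feature extractor and its receptive-field arithmetic.

The backbone is a stack of five blocks, each Conv3d -> BatchNorm3d -> ReLU ->
ceil-mode MaxPool3d (stride 2).  With the default configuration an
``80x100x80`` hippocampal patch maps to 128 feature maps of spatial size
``(3, 4, 3)``; the flattened feature vector h has length 128*3*4*3 = 4608.

The receptive-field recursion

    l_k = l_{k-1} + (f_k - 1) * prod_{i<k} s_i,    l_0 = 1

is exposed for any flattened (kernel, stride) layer list.  Applied to the
pooling stack alone (five kernel-2/stride-2 layers) it gives 32, i.e. each
output voxel of the downsampling chain summarises a 32x32x32 input region;
including the 3^3 convolutions enlarges the field further.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .volume_io import VolumePatch


@dataclass(frozen=True)
class BlockSpec:
    """One conv/batch-norm/ReLU/padded-max-pool block."""

    out_channels: int
    conv_kernel: int = 3
    conv_stride: int = 1
    pool_kernel: int = 2
    pool_stride: int = 2

    def __post_init__(self):
        for name in ("out_channels", "conv_kernel", "conv_stride", "pool_kernel", "pool_stride"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class ArchitectureSpec:
    blocks: tuple[BlockSpec, ...]
    input_shape: tuple[int, int, int] = (80, 100, 80)

    def __post_init__(self):
        self.blocks = tuple(self.blocks)
        if not self.blocks:
            raise ValueError("ArchitectureSpec needs at least one block")
        self.input_shape = tuple(int(s) for s in self.input_shape)

    @property
    def out_channels(self) -> int:
        return self.blocks[-1].out_channels

    def layer_sequence(self, include_convs: bool = True) -> list[tuple[int, int]]:
        """Flattened (kernel, stride) list; convolutions optionally omitted
        to obtain the pure downsampling (pooling) stack."""
        layers = []
        for b in self.blocks:
            if include_convs:
                layers.append((b.conv_kernel, b.conv_stride))
            layers.append((b.pool_kernel, b.pool_stride))
        return layers

    def output_shape(self) -> tuple[int, tuple[int, int, int]]:
        """(channels, spatial shape) after the full block stack."""
        extents = list(self.input_shape)
        for b in self.blocks:
            extents = [math.ceil(e / b.conv_stride) for e in extents]  # 'same' conv
            extents = [math.ceil(e / b.pool_stride) for e in extents]  # ceil-mode pool
        return self.out_channels, tuple(extents)

    def flat_dim(self) -> int:
        c, spatial = self.output_shape()
        return c * int(np.prod(spatial))


#: Channel progression of the shipped default backbone.
DEFAULT_CHANNELS = (8, 16, 32, 64, 128)


def default_spec(input_shape: tuple[int, int, int] = (80, 100, 80),
                 channels: tuple[int, ...] = DEFAULT_CHANNELS) -> ArchitectureSpec:
    return ArchitectureSpec(tuple(BlockSpec(out_channels=c) for c in channels),
                            input_shape=input_shape)


def receptive_field(layers) -> list[int]:
    """Receptive-field side length after each layer of a flattened stack.

    ``layers`` is an :class:`ArchitectureSpec` (convs included) or any
    iterable of ``(kernel, stride)`` pairs.  Starting from l_0 = 1, each layer
    adds ``(f_k - 1)`` times the product of all upstream strides.  The result
    is strictly nondecreasing and independent of channel counts.
    """
    if isinstance(layers, ArchitectureSpec):
        layers = layers.layer_sequence(include_convs=True)
    sizes = []
    l, jump = 1, 1
    for f, s in layers:
        if f < 1 or s < 1:
            raise ValueError("kernels and strides must be >= 1")
        l = l + (f - 1) * jump
        jump *= s
        sizes.append(l)
    return sizes


@dataclass
class FeatureVolume:
    """Backbone output for one patch: (channels, depth, height, width)."""

    data: np.ndarray
    source_shape: tuple[int, int, int]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"FeatureVolume data must be 4-D, got {self.data.ndim}-D")

    @property
    def channels(self) -> int:
        return self.data.shape[0]


def flatten(fv: FeatureVolume) -> np.ndarray:
    """Channel-major flatten: element (c, z, y, x) of a (C, D, H, W) feature
    volume lands at index ``((c*D + z)*H + y)*W + x``."""
    return np.ascontiguousarray(fv.data).ravel()


class Backbone:
    """Trainable realisation of an :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        for b in spec.blocks:
            if b.conv_stride != 1:
                raise NotImplementedError("only stride-1 convolutions are implemented")
            if b.pool_kernel != b.pool_stride:
                raise NotImplementedError("pooling requires kernel == stride")
        self.spec = spec
        layers: list[nn.Layer] = []
        c_in = 1
        for b in spec.blocks:
            layers += [nn.Conv3d(c_in, b.out_channels, kernel=b.conv_kernel, rng=rng),
                       nn.BatchNorm3d(b.out_channels),
                       nn.ReLU(),
                       nn.PadMaxPool3d(kernel=b.pool_kernel)]
            c_in = b.out_channels
        self.net = nn.Sequential(layers)

    def params(self):
        return self.net.params()

    def forward_batch(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """x: (N, 1, D, H, W) -> (N, C, d, h, w)."""
        if x.ndim != 5 or tuple(x.shape[2:]) != self.spec.input_shape:
            raise ValueError(
                f"input shape mismatch: expected (N, 1, {self.spec.input_shape}), "
                f"got {x.shape}")
        return self.net.forward(x.astype(nn.DTYPE), training=training)

    def backward_batch(self, gout: np.ndarray) -> np.ndarray:
        return self.net.backward(gout)

    def forward(self, patch: VolumePatch | np.ndarray, training: bool = False) -> FeatureVolume:
        """Forward a single patch; returns a :class:`FeatureVolume`."""
        data = patch.data if isinstance(patch, VolumePatch) else np.asarray(patch)
        if data.shape != self.spec.input_shape:
            raise ValueError(
                f"patch shape mismatch: expected {self.spec.input_shape}, got {data.shape}")
        out = self.forward_batch(data[None, None], training=training)
        return FeatureVolume(out[0], source_shape=tuple(data.shape))


def forward(spec_or_backbone, patch, rng: np.random.Generator | None = None) -> FeatureVolume:
    """Functional forward: builds a randomly initialised backbone if a bare
    spec is given (useful for shape-contract checks)."""
    bb = (spec_or_backbone if isinstance(spec_or_backbone, Backbone)
          else Backbone(spec_or_backbone, rng=rng))
    return bb.forward(patch)
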