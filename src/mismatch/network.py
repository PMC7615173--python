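"""Encoder + two attention-shifting decoders, and the supervised baseline.

The semi-supervised network shares one U-net-style encoder between two
decoders: decoder 1 is built from positive (dilating) attention blocks,
decoder 2 from negative (eroding) attention blocks.  Each decoder ends in a
1x1 conv + sigmoid head producing a foreground probability map; the final
prediction is the elementwise average of the two heads.  Ablation variants
swap either decoder for a plain one:

===========  =====================  =====================
variant      decoder 1              decoder 2
===========  =====================  =====================
``MM``       positive attention     negative attention
``MM-a``     plain                  plain
``MM-b``     plain                  negative attention
``MM-c``     plain                  positive attention
===========  =====================  =====================

A ``UNet`` with a single plain decoder of the same width serves as the
supervised baseline.  Both 2-D slices (N, C, H, W) and 3-D volumes
(N, C, D, H, W) are supported; the 3-D variant simply swaps every conv for
its 3-D counterpart.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .blocks import BlockSpec, make_block
from .nn import Conv, Module, Tensor, concat, max_pool, upsample_nearest

__all__ = ["NetworkSpec", "PairedPrediction", "MisMatchNet", "UNet",
           "build_network", "build_baseline", "save_network", "load_network"]

_VARIANTS = {
    "MM": ("pasb", "nasb"),
    "MM-a": ("plain", "plain"),
    "MM-b": ("plain", "nasb"),
    "MM-c": ("plain", "pasb"),
}


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture configuration.

    base_width is the channel count of the first encoder stage (the
    reference settings are 24 for 2-D and 8 for 3-D); depth is the number of
    resolution levels, so spatial extents must be divisible by
    ``2**(depth-1)``.
    """

    dims: int = 2
    in_channels: int = 1
    base_width: int = 24
    depth: int = 3
    decoder_variant: str = "MM"
    main_kernel: int = 3
    side_dilation: int = 5
    norm_kind: str = "instance"
    gate_mode: str = "multiply"
    seed: int = 0
    tie_decoder_init: bool = False

    def __post_init__(self):
        if self.dims not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.dims}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.decoder_variant not in _VARIANTS:
            raise ValueError(
                f"decoder_variant must be one of {sorted(_VARIANTS)}, "
                f"got {self.decoder_variant!r}")

    @property
    def widths(self) -> list[int]:
        return [self.base_width * 2 ** i for i in range(self.depth)]

    @property
    def spatial_multiple(self) -> int:
        return 2 ** (self.depth - 1)


@dataclass
class PairedPrediction:
    """Per-decoder probability maps and their average."""

    p1: Tensor
    p2: Tensor
    fused: Tensor


def _block_spec(spec: NetworkSpec, kind: str, cin: int, cout: int) -> BlockSpec:
    return BlockSpec(in_channels=cin, out_channels=cout, nd=spec.dims,
                     block_kind=kind, main_kernel=spec.main_kernel,
                     side_dilation=spec.side_dilation, norm_kind=spec.norm_kind,
                     gate_mode=spec.gate_mode)


class Encoder(Module):
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        w = spec.widths
        self.blocks = [make_block(_block_spec(spec, "plain", spec.in_channels, w[0]), rng)]
        for i in range(1, spec.depth):
            self.blocks.append(make_block(_block_spec(spec, "plain", w[i - 1], w[i]), rng))

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = [self.blocks[0](x)]
        for block in self.blocks[1:]:
            feats.append(block(max_pool(feats[-1])))
        return feats


class Decoder(Module):
    """Upsample-concat-block ladder ending in a 1x1 conv + sigmoid head."""

    def __init__(self, spec: NetworkSpec, kind: str, rng: np.random.Generator):
        w = spec.widths
        self.blocks = []
        for i in range(spec.depth - 2, -1, -1):
            self.blocks.append(
                make_block(_block_spec(spec, kind, w[i + 1] + w[i], w[i]), rng))
        self.head = Conv(w[0], 1, 1, spec.dims, rng=rng)

    def forward(self, feats: list[Tensor]) -> Tensor:
        y = feats[-1]
        for skip, block in zip(reversed(feats[:-1]), self.blocks):
            y = block(concat([upsample_nearest(y), skip], axis=1))
        return self.head(y).sigmoid()


def _check_spatial(spec: NetworkSpec, x: Tensor) -> None:
    if x.ndim != spec.dims + 2:
        raise ValueError(
            f"expected a (batch, channel, *spatial) array with {spec.dims} "
            f"spatial dims, got shape {x.shape}")
    m = spec.spatial_multiple
    if any(s % m for s in x.shape[2:]):
        raise ValueError(
            f"spatial dims {x.shape[2:]} must all be divisible by {m} "
            f"for depth {spec.depth}")


class MisMatchNet(Module):
    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        kinds = _VARIANTS[spec.decoder_variant]
        rng_e = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, 0)))
        rng_1 = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, 1)))
        seed2 = 1 if spec.tie_decoder_init else 2
        rng_2 = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, seed2)))
        self.encoder = Encoder(spec, rng_e)
        self.decoder1 = Decoder(spec, kinds[0], rng_1)
        self.decoder2 = Decoder(spec, kinds[1], rng_2)

    def forward(self, x: Tensor) -> PairedPrediction:
        _check_spatial(self.spec, x)
        feats = self.encoder(x)
        p1 = self.decoder1(feats)
        p2 = self.decoder2(feats)
        return PairedPrediction(p1=p1, p2=p2, fused=(p1 + p2) * 0.5)


class UNet(Module):
    """Single plain-decoder network of matching width: the supervised baseline."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng_e = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, 0)))
        rng_d = np.random.default_rng(np.random.SeedSequence(entropy=(spec.seed, 1)))
        self.encoder = Encoder(spec, rng_e)
        self.decoder = Decoder(spec, "plain", rng_d)

    def forward(self, x: Tensor) -> PairedPrediction:
        _check_spatial(self.spec, x)
        p = self.decoder(self.encoder(x))
        return PairedPrediction(p1=p, p2=p, fused=p)


def build_network(spec: NetworkSpec) -> MisMatchNet:
    return MisMatchNet(spec)


def build_baseline(spec: NetworkSpec) -> UNet:
    return UNet(spec)


def save_network(path, network: Module) -> None:
    """Serialise spec + parameters to an ``.npz`` checkpoint."""
    state = network.state_dict()
    meta = {"spec": asdict(network.spec),
            "kind": type(network).__name__, "format_version": 1}
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_network(path) -> Module:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    spec = NetworkSpec(**meta["spec"])
    network = {"MisMatchNet": MisMatchNet, "UNet": UNet}[meta["kind"]](spec)
    network.load_state_dict(state)
    return network
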