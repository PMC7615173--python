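"""Decoder building blocks: plain, positive-attention and negative-attention.

The plain block is the standard two-conv decoder stage.  The two attention
blocks add a parallel side branch whose sigmoid output gates the main
branch:

* the positive block's side branch is a single dilated convolution, so the
  gate's effective receptive field (ERF) is larger than the main branch's —
  high-confidence foreground features get dilated;
* the negative block's side branch mirrors the main branch but wraps each
  conv stage in an identity skip connection, shrinking the gate's ERF —
  high-confidence foreground features get eroded.

Both gates multiply the main branch output elementwise.  The alternative
residual-attention combination ``main * (1 + gate)`` is available behind
``BlockSpec.gate_mode`` for ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import Conv, Identity, InstanceNorm, Module, Tensor

__all__ = ["BlockSpec", "PlainBlock", "PositiveAttentionBlock",
           "NegativeAttentionBlock", "make_block"]

_BLOCK_KINDS = ("plain", "pasb", "nasb")
_NORM_KINDS = ("instance", "none")
_GATE_MODES = ("multiply", "residual")


@dataclass(frozen=True)
class BlockSpec:
    """Configuration of one decoder block.

    side_dilation is the dilation rate of the positive block's side conv
    (default 5, giving an effective footprint of 11 pixels for a 3-kernel);
    norm_kind defaults to instance normalisation because the reference
    training setting uses batch size 1.
    """

    in_channels: int
    out_channels: int
    nd: int = 2
    block_kind: str = "plain"
    main_kernel: int = 3
    side_dilation: int = 5
    norm_kind: str = "instance"
    gate_mode: str = "multiply"
    seed: int = 0

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.main_kernel % 2 == 0 or self.main_kernel < 1:
            raise ValueError(f"main_kernel must be odd, got {self.main_kernel}")
        if self.side_dilation < 1:
            raise ValueError("side_dilation must be >= 1")
        if self.block_kind not in _BLOCK_KINDS:
            raise ValueError(f"block_kind must be one of {_BLOCK_KINDS}")
        if self.norm_kind not in _NORM_KINDS:
            raise ValueError(f"norm_kind must be one of {_NORM_KINDS}")
        if self.gate_mode not in _GATE_MODES:
            raise ValueError(f"gate_mode must be one of {_GATE_MODES}")


def _norm(spec: BlockSpec, channels: int) -> Module:
    if spec.norm_kind == "instance":
        return InstanceNorm(channels, nd=spec.nd)
    return Identity()


class PlainBlock(Module):
    """Two (conv -> ReLU -> norm) stages; spatial shape preserved."""

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        if spec.block_kind != "plain":
            raise ValueError(f"expected a plain spec, got {spec.block_kind!r}")
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        k, nd = spec.main_kernel, spec.nd
        self.conv1 = Conv(spec.in_channels, spec.out_channels, k, nd, rng=rng)
        self.norm1 = _norm(spec, spec.out_channels)
        self.conv2 = Conv(spec.out_channels, spec.out_channels, k, nd, rng=rng)
        self.norm2 = _norm(spec, spec.out_channels)

    def forward(self, x: Tensor) -> Tensor:
        x = self.norm1(self.conv1(x).relu())
        return self.norm2(self.conv2(x).relu())


class _GatedBlock(Module):
    """Shared main-branch + gate plumbing for the two attention blocks."""

    def __init__(self, spec: BlockSpec, rng: np.random.Generator):
        self.main = PlainBlock(replace(spec, block_kind="plain"), rng=rng)
        self.gate_mode = spec.gate_mode

    def side(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, x: Tensor) -> Tensor:
        main = self.main(x)
        gate = self.side(x).sigmoid()
        if self.gate_mode == "residual":
            return main * (gate + 1.0)
        return main * gate


class PositiveAttentionBlock(_GatedBlock):
    """Main branch gated by a single dilated-conv side branch (larger ERF)."""

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        if spec.block_kind != "pasb":
            raise ValueError(f"expected a pasb spec, got {spec.block_kind!r}")
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        super().__init__(spec, rng)
        self.side_conv = Conv(spec.in_channels, spec.out_channels,
                              spec.main_kernel, spec.nd,
                              dilation=spec.side_dilation, rng=rng)

    def side(self, x: Tensor) -> Tensor:
        return self.side_conv(x)


class NegativeAttentionBlock(_GatedBlock):
    """Main branch gated by a residual side branch (smaller ERF).

    The side branch mirrors the main branch's two conv stages but wraps each
    in an identity skip; a 1x1 projection aligns channels on the first skip
    when in_channels != out_channels.
    """

    def __init__(self, spec: BlockSpec, rng: np.random.Generator | None = None):
        if spec.block_kind != "nasb":
            raise ValueError(f"expected a nasb spec, got {spec.block_kind!r}")
        rng = rng if rng is not None else np.random.default_rng(spec.seed)
        super().__init__(spec, rng)
        k, nd = spec.main_kernel, spec.nd
        self.side_conv1 = Conv(spec.in_channels, spec.out_channels, k, nd, rng=rng)
        self.side_norm1 = _norm(spec, spec.out_channels)
        if spec.in_channels != spec.out_channels:
            self.side_proj = Conv(spec.in_channels, spec.out_channels, 1, nd, rng=rng)
        else:
            self.side_proj = Identity()
        self.side_conv2 = Conv(spec.out_channels, spec.out_channels, k, nd, rng=rng)
        self.side_norm2 = _norm(spec, spec.out_channels)

    def side(self, x: Tensor) -> Tensor:
        y = self.side_proj(x) + self.side_norm1(self.side_conv1(x).relu())
        return y + self.side_norm2(self.side_conv2(y).relu())


def make_block(spec: BlockSpec, rng: np.random.Generator | None = None) -> Module:
    """Instantiate the block described by ``spec`` (weights from its seed)."""
    cls = {"plain": PlainBlock, "pasb": PositiveAttentionBlock,
           "nasb": NegativeAttentionBlock}[spec.block_kind]
    return cls(spec, rng=rng)
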