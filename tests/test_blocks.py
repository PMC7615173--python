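"""Decoder block semantics: gating arithmetic, shape preservation, ERF
ordering of the attention pathways."""

import numpy as np
import pytest
from scipy.stats import binomtest

from mismatch.blocks import (BlockSpec, NegativeAttentionBlock, PlainBlock,
                             PositiveAttentionBlock, make_block)
from mismatch.erf import erf_block_ordering
from mismatch.nn import Tensor

RNG = np.random.default_rng(7)


def zero_params(module):
    for p in module.parameters():
        p.data[...] = 0.0


class TestPlainBlock:
    def test_zero_weights_give_zero_output(self):
        block = make_block(BlockSpec(in_channels=2, out_channels=3, seed=0))
        zero_params(block)
        x = Tensor(RNG.normal(size=(1, 2, 8, 8)))
        np.testing.assert_array_equal(block(x).data, 0.0)

    def test_identity_1x1_kernels_reduce_to_relu(self):
        spec = BlockSpec(in_channels=1, out_channels=1, main_kernel=1,
                         norm_kind="none", seed=0)
        block = make_block(spec)
        for conv in (block.conv1, block.conv2):
            conv.weight.data[...] = 1.0
            conv.bias.data[...] = 0.0
        x = RNG.normal(size=(1, 1, 6, 6))
        np.testing.assert_allclose(block(Tensor(x)).data, np.maximum(x, 0.0))

    def test_fixed_seed_is_deterministic(self):
        x = Tensor(RNG.normal(size=(1, 2, 8, 8)))
        out1 = make_block(BlockSpec(in_channels=2, out_channels=4, seed=5))(x)
        out2 = make_block(BlockSpec(in_channels=2, out_channels=4, seed=5))(x)
        np.testing.assert_array_equal(out1.data, out2.data)


class TestGatedBlocks:
    @pytest.mark.parametrize("kind", ["pasb", "nasb"])
    def test_zero_side_gives_half_gate(self, kind):
        """sigmoid(0) = 0.5: zeroed side branch halves the main output."""
        spec = BlockSpec(in_channels=2, out_channels=2, block_kind=kind, seed=1)
        block = make_block(spec)
        x = Tensor(np.zeros((1, 2, 8, 8)))
        if kind == "pasb":
            block.side_conv.weight.data[...] = 0.0
            block.side_conv.bias.data[...] = 0.0
        # x == 0 zeroes the nasb side (identity skips of zero) already
        main = block.main(x)
        np.testing.assert_allclose(block(x).data, 0.5 * main.data, atol=1e-12)

    def test_pasb_saturated_gate_passes_main_through(self):
        spec = BlockSpec(in_channels=1, out_channels=1, block_kind="pasb", seed=2)
        block = make_block(spec)
        block.side_conv.weight.data[...] = 0.0
        block.side_conv.bias.data[...] = 20.0
        x = Tensor(RNG.normal(size=(1, 1, 8, 8)))
        np.testing.assert_allclose(block(x).data, block.main(x).data, rtol=1e-6)

    def test_pasb_hand_computed_gate(self):
        """main 2.0 with side pre-activation 0 gives 2.0 * 0.5 = 1.0."""
        spec = BlockSpec(in_channels=1, out_channels=1, main_kernel=1,
                         norm_kind="none", block_kind="pasb", seed=0)
        block = make_block(spec)
        block.main.conv1.weight.data[...] = 1.0
        block.main.conv2.weight.data[...] = 1.0
        block.main.conv2.bias.data[...] = 1.0
        block.side_conv.weight.data[...] = 0.0
        block.side_conv.bias.data[...] = 0.0
        x = Tensor(np.ones((1, 1, 3, 3)))  # main: relu(relu(1)+1) = 2
        np.testing.assert_allclose(block(x).data, 1.0, atol=1e-12)

    def test_nasb_zero_convs_reduce_side_to_skips(self):
        spec = BlockSpec(in_channels=2, out_channels=2, block_kind="nasb", seed=3)
        block = make_block(spec)
        for conv in (block.side_conv1, block.side_conv2):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        x = RNG.normal(size=(1, 2, 8, 8))
        side = block.side(Tensor(x))
        np.testing.assert_allclose(side.data, x, atol=1e-12)

    def test_nasb_channel_mismatch_uses_projection(self):
        spec = BlockSpec(in_channels=3, out_channels=5, block_kind="nasb", seed=0)
        block = make_block(spec)
        out = block(Tensor(RNG.normal(size=(1, 3, 8, 8))))
        assert out.shape == (1, 5, 8, 8)

    @pytest.mark.parametrize("kind", ["pasb", "nasb"])
    def test_gate_bounds_output_by_main(self, kind):
        spec = BlockSpec(in_channels=2, out_channels=4, block_kind=kind, seed=4)
        block = make_block(spec)
        x = Tensor(RNG.normal(size=(2, 2, 8, 8)))
        out, main = block(x), block.main(x)
        assert np.all(np.abs(out.data) <= np.abs(main.data) + 1e-12)
        gate = block.side(x).sigmoid().data
        assert np.all((gate > 0.0) & (gate < 1.0))

    def test_residual_gate_mode_amplifies(self):
        spec = BlockSpec(in_channels=1, out_channels=2, block_kind="pasb",
                         gate_mode="residual", seed=4)
        block = make_block(spec)
        x = Tensor(RNG.normal(size=(1, 1, 8, 8)))
        out, main = block(x), block.main(x)
        assert np.all(np.abs(out.data) >= np.abs(main.data) - 1e-12)


class TestShapeContract:
    @pytest.mark.parametrize("kind", ["plain", "pasb", "nasb"])
    @pytest.mark.parametrize("kernel, dilation", [(3, 5), (5, 2), (1, 1)])
    def test_spatial_shape_preserved_2d(self, kind, kernel, dilation):
        spec = BlockSpec(in_channels=2, out_channels=3, block_kind=kind,
                         main_kernel=kernel, side_dilation=dilation, seed=0)
        out = make_block(spec)(Tensor(RNG.normal(size=(1, 2, 10, 12))))
        assert out.shape == (1, 3, 10, 12)

    @pytest.mark.parametrize("kind", ["plain", "pasb", "nasb"])
    def test_spatial_shape_preserved_3d(self, kind):
        spec = BlockSpec(in_channels=1, out_channels=2, nd=3, block_kind=kind, seed=0)
        out = make_block(spec)(Tensor(RNG.normal(size=(1, 1, 6, 8, 6))))
        assert out.shape == (1, 2, 6, 8, 6)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            BlockSpec(in_channels=0, out_channels=1)
        with pytest.raises(ValueError):
            BlockSpec(in_channels=1, out_channels=1, main_kernel=4)
        with pytest.raises(ValueError):
            BlockSpec(in_channels=1, out_channels=1, block_kind="magic")


class TestGradientFlow:
    @pytest.mark.parametrize("kind", ["pasb", "nasb"])
    def test_both_branches_receive_gradient(self, kind):
        spec = BlockSpec(in_channels=1, out_channels=1, block_kind=kind,
                         norm_kind="none", seed=6)
        block = make_block(spec)
        x = Tensor(RNG.normal(size=(1, 1, 6, 6)))
        (block(x) ** 2.0).sum().backward()
        grads = {name: p.grad for name, p in block.named_parameters()}
        assert any("main" in n and g is not None and np.abs(g).sum() > 0
                   for n, g in grads.items())
        assert any("side" in n and g is not None and np.abs(g).sum() > 0
                   for n, g in grads.items())

    def test_autodiff_matches_finite_difference_on_toy(self):
        spec = BlockSpec(in_channels=1, out_channels=1, block_kind="pasb",
                         norm_kind="none", seed=8)
        block = make_block(spec)
        x0 = RNG.normal(size=(1, 1, 5, 5))
        x = Tensor(x0, requires_grad=True)
        (block(x) ** 2.0).sum().backward()
        eps = 1e-5
        num = np.zeros_like(x0)
        it = np.nditer(x0, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            xp, xm = x0.copy(), x0.copy()
            xp[idx] += eps
            xm[idx] -= eps
            num[idx] = ((block(Tensor(xp)).data ** 2).sum()
                        - (block(Tensor(xm)).data ** 2).sum()) / (2 * eps)
        np.testing.assert_allclose(x.grad, num, rtol=1e-4, atol=1e-8)


class TestErfOrdering:
    def test_attention_pathways_order_by_mean_erf(self):
        """Dilating gate sees widest, eroding gate narrowest, on average."""
        df = erf_block_ordering(n_seeds=6, seed=0)
        means = df.groupby("kind")["support_area"].mean()
        assert means["pasb"] > means["plain"] > means["nasb"]
        radii = df.groupby("kind")["rms_radius"].mean()
        assert radii["pasb"] > radii["plain"] > radii["nasb"]

    def test_pathway_ordering_holds_per_seed(self):
        df = erf_block_ordering(n_seeds=8, seed=0)
        wide = df.pivot(index="seed", columns="kind", values="rms_radius")
        n = len(wide)
        assert binomtest(int((wide["pasb"] > wide["plain"]).sum()), n,
                         alternative="greater").pvalue < 0.05
        assert binomtest(int((wide["plain"] > wide["nasb"]).sum()), n,
                         alternative="greater").pvalue < 0.05
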