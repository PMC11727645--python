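"""The novel building blocks, each checked against an independent oracle."""

import numpy as np
import pytest
from scipy import ndimage

from vdmnet import nn
from vdmnet.autodiff import Tensor, no_grad, softmax
from vdmnet.blocks import (
    MSF,
    BasicBlock,
    ExpertWeights,
    FastMHSADecoder,
    FastMHSAEncoder,
    OffsetPredictor,
    VDConv,
    VesselTransformerDecoder,
    VesselTransformerEncoder,
    deformable_conv,
    fast_attention,
    fit_pool_size,
    subsample_kv,
)


def brute_force_attention(q, k, v):
    """O(n^2) reference: softmax over explicit score matrix, plain loops."""
    n, d = q.shape
    m = k.shape[0]
    out = np.zeros((n, v.shape[1]))
    for i in range(n):
        scores = np.array([q[i] @ k[j] / np.sqrt(d) for j in range(m)])
        scores -= scores.max()
        w = np.exp(scores)
        w /= w.sum()
        out[i] = w @ v
    return out


def reference_conv3x3(x, w, dilation=1):
    """Independent standard-convolution oracle via scipy correlate."""
    n, cin, h, wdt = x.shape
    cout = w.shape[0]
    out = np.zeros((n, cout, h, wdt))
    if dilation > 1:
        kd = np.zeros((cout, cin, 2 * dilation + 1, 2 * dilation + 1))
        kd[:, :, ::dilation, ::dilation] = w
        w = kd
    for b in range(n):
        for o in range(cout):
            acc = np.zeros((h, wdt))
            for c in range(cin):
                acc += ndimage.correlate(x[b, c], w[o, c], mode="constant")
            out[b, o] = acc
    return out


class TestFastAttention:
    def test_equals_bruteforce_when_unpooled(self, rng):
        q = rng.normal(size=(10, 4))
        k = rng.normal(size=(10, 4))
        v = rng.normal(size=(10, 4))
        got = fast_attention(Tensor(q), Tensor(k), Tensor(v)).data
        assert np.abs(got - brute_force_attention(q, k, v)).max() < 1e-5

    def test_constant_values_collapse(self, rng):
        q = rng.normal(size=(6, 3))
        k = rng.normal(size=(4, 3))
        v = np.tile([1.5, -2.0, 0.5], (4, 1))
        got = fast_attention(Tensor(q), Tensor(k), Tensor(v)).data
        assert np.allclose(got, v[0])

    def test_single_token(self, rng):
        q = rng.normal(size=(1, 5))
        k = rng.normal(size=(1, 5))
        v = rng.normal(size=(1, 5))
        assert np.allclose(fast_attention(Tensor(q), Tensor(k), Tensor(v)).data, v)

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shapes"):
            fast_attention(Tensor(rng.normal(size=(4, 3))),
                           Tensor(rng.normal(size=(2, 5))),
                           Tensor(rng.normal(size=(2, 5))))

    def test_rows_of_attention_matrix_sum_to_one(self, rng):
        q = Tensor(rng.normal(size=(7, 4)))
        k = Tensor(rng.normal(size=(3, 4)))
        p = softmax((q @ k.transpose(1, 0)) * (1 / 2.0), axis=-1)
        assert np.allclose(p.data.sum(axis=-1), 1.0)


class TestSubsampleKV:
    def test_identity_at_full_size(self, rng):
        k = rng.normal(size=(2, 12, 5))
        v = rng.normal(size=(2, 12, 5))
        kb, vb = subsample_kv(Tensor(k), Tensor(v), (3, 4), (3, 4))
        assert np.allclose(kb.data, k) and np.allclose(vb.data, v)

    def test_constant_preserved(self):
        k = np.full((1, 16, 3), 2.5)
        kb, _ = subsample_kv(Tensor(k), Tensor(k), (4, 4), (2, 2))
        assert np.allclose(kb.data, 2.5)

    def test_hand_computed_block_means(self):
        vals = np.arange(16, dtype=float).reshape(1, 16, 1)
        kb, _ = subsample_kv(Tensor(vals), Tensor(vals), (4, 4), (2, 2))
        grid = np.arange(16).reshape(4, 4)
        expected = [grid[:2, :2].mean(), grid[:2, 2:].mean(),
                    grid[2:, :2].mean(), grid[2:, 2:].mean()]
        assert np.allclose(kb.data[0, :, 0], expected)

    def test_upsampling_rejected(self, rng):
        k = Tensor(rng.normal(size=(1, 4, 2)))
        with pytest.raises(ValueError, match="exceeds"):
            subsample_kv(k, k, (2, 2), (4, 4))

    def test_fit_pool_size_divisor(self):
        assert fit_pool_size(64, 8) == 8
        assert fit_pool_size(38, 8) == 2
        assert fit_pool_size(6, 8) == 6


class TestOffsetPredictor:
    def test_bounded_offsets(self, rng):
        head = OffsetPredictor(4)
        for _ in range(10):
            o = head(Tensor(rng.normal(size=(1, 4, 8, 8), scale=5)))
            assert np.abs(o.data).max() <= 1.0

    def test_zeroed_head_gives_zero_offsets(self, rng):
        head = OffsetPredictor(4)
        head.conv.weight.data[...] = 0
        head.conv.bias.data[...] = 0
        o = head(Tensor(rng.normal(size=(2, 4, 6, 6))))
        assert np.allclose(o.data, 0.0)

    def test_channel_count_contract(self, rng):
        head = OffsetPredictor(3, k_positions=9)
        o = head(Tensor(rng.normal(size=(1, 3, 8, 8))))
        assert o.shape == (1, 18, 8, 8)


class TestDeformableConv:
    def test_zero_offsets_equal_standard_convolution(self, rng):
        x = rng.normal(size=(2, 3, 8, 8))
        w = rng.normal(size=(4, 3, 3, 3))
        offsets = np.zeros((2, 18, 8, 8))
        got = deformable_conv(Tensor(x), Tensor(offsets), Tensor(w)).data
        assert np.abs(got - reference_conv3x3(x, w)).max() < 1e-5

    def test_constant_input_in_bounds(self, rng):
        x = np.full((1, 2, 10, 10), 1.7)
        w = rng.normal(size=(3, 2, 3, 3))
        offsets = Tensor(rng.uniform(-1, 1, size=(1, 18, 10, 10)))
        got = deformable_conv(Tensor(x), offsets, Tensor(w), offset_scale=0.5).data
        expected = 1.7 * w.sum(axis=(1, 2, 3))
        interior = got[0, :, 3:-3, 3:-3]
        assert np.allclose(interior, expected[:, None, None], atol=1e-9)

    def test_integer_offsets_match_gather(self, rng):
        x = rng.normal(size=(1, 1, 6, 6))
        w = np.zeros((1, 1, 3, 3))
        w[0, 0, 1, 1] = 1.0  # center tap only: output = gathered input
        offsets = np.zeros((1, 18, 6, 6))
        offsets[0, 2 * 4] = 1.0      # center tap y-offset +1
        got = deformable_conv(Tensor(x), Tensor(offsets), Tensor(w), offset_scale=1.0).data
        expected = np.zeros((6, 6))
        expected[:5] = x[0, 0, 1:]   # shifted up gather, zero pad at bottom
        assert np.abs(got[0, 0] - expected).max() < 1e-12


class TestExpertWeights:
    def test_simplex(self, rng):
        gate = ExpertWeights(6, 4)
        a = gate(Tensor(rng.normal(size=(3, 6, 8, 8)))).data
        assert a.shape == (3, 4, 1, 1)
        assert np.all(a >= 0) and np.allclose(a.sum(axis=1), 1.0)

    def test_single_expert(self, rng):
        gate = ExpertWeights(6, 1)
        a = gate(Tensor(rng.normal(size=(2, 6, 4, 4)))).data
        assert np.allclose(a, 1.0)

    def test_softmax_closed_form(self):
        logits = Tensor(np.array([2.0, 0.0]).reshape(1, 2, 1, 1))
        a = softmax(logits, axis=1).data.ravel()
        assert a == pytest.approx([np.e**2 / (np.e**2 + 1), 1 / (np.e**2 + 1)], abs=1e-4)


class TestVDConv:
    def _zero_offsets(self, vd):
        vd.offset_head.conv.weight.data[...] = 0
        vd.offset_head.conv.bias.data[...] = 0

    def test_single_expert_zero_offsets_is_grouped_conv(self, rng):
        vd = VDConv(4, 4, n_experts=1, groups=2)
        self._zero_offsets(vd)
        x = rng.normal(size=(1, 4, 8, 8))
        got = vd(Tensor(x)).data
        w = vd.expert_kernels.data[0]  # (4, 2, 3, 3) grouped
        expected = np.zeros_like(got)
        for g in range(2):
            xg = x[:, 2 * g: 2 * g + 2]
            wg = w[2 * g: 2 * g + 2]
            expected[:, 2 * g: 2 * g + 2] = reference_conv3x3(xg, wg)
        expected += vd.bias.data.reshape(1, -1, 1, 1)
        assert np.abs(got - expected).max() < 1e-5

    def test_one_hot_gate_selects_single_expert(self, rng):
        vd = VDConv(4, 4, n_experts=3)
        vd.expert_gate.gate.weight.data[...] = 0
        vd.expert_gate.gate.bias.data[...] = np.array([0.0, 50.0, 0.0])
        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        offsets = vd.offset_head(x)
        sampled = nn.deform_sample(x, offsets, offset_scale=vd.offset_scale)
        w1 = vd.expert_kernels[1].reshape(4, 4 * 9, 1, 1)
        y1 = nn.conv2d(sampled, w1).data + vd.bias.data.reshape(1, -1, 1, 1)
        assert np.abs(vd(x).data - y1).max() < 1e-9

    def test_fusion_is_convex_combination(self, rng):
        vd = VDConv(2, 2, n_experts=2)
        vd.expert_gate.gate.weight.data[...] = 0
        vd.expert_gate.gate.bias.data[...] = 0  # alpha = (0.5, 0.5)
        self._zero_offsets(vd)
        x = rng.normal(size=(1, 2, 6, 6))
        ys = [reference_conv3x3(x, vd.expert_kernels.data[n]) for n in range(2)]
        expected = 0.5 * ys[0] + 0.5 * ys[1] + vd.bias.data.reshape(1, -1, 1, 1)
        assert np.abs(vd(Tensor(x)).data - expected).max() < 1e-5

    def test_divisibility_rejected(self):
        with pytest.raises(ValueError, match="groups"):
            VDConv(5, 4, groups=2)


class TestMSF:
    def test_shape_preserved(self, rng):
        msf = MSF(6)
        x = Tensor(rng.normal(size=(2, 6, 12, 12)))
        assert msf(x).shape == x.shape

    def test_zeroed_branches_residual_identity(self, rng):
        msf = MSF(4)
        msf.compress.weight.data[...] = 0
        msf.compress.bias.data[...] = 0
        x = rng.normal(size=(1, 4, 8, 8))
        assert np.allclose(msf(Tensor(x)).data, x)

    def test_dilated_branch_sees_three_pixels_out(self, rng):
        """An impulse 3 px from center reaches the dilation-3 branch's 7x7
        receptive field but not the 1x1 branch."""
        msf = MSF(1)
        msf.eval()  # frozen BN: keeps each branch spatially local
        x = np.zeros((1, 1, 15, 15))
        base = np.array([b(Tensor(x)).data.copy() for b in msf.branches])
        x[0, 0, 7 + 3, 7] = 1.0  # impulse 3 px below center
        resp = np.array([b(Tensor(x)).data.copy() for b in msf.branches])
        delta_center = np.abs(resp - base)[:, 0, 0, 7, 7]
        assert delta_center[3] > 1e-8   # dilation-3 branch responds at center
        assert delta_center[0] < 1e-12  # 1x1 branch cannot


class TestBasicBlock:
    def test_output_channels_contract(self, rng):
        block = BasicBlock(3, 7)
        y = block(Tensor(rng.normal(size=(2, 3, 10, 10))))
        assert y.shape == (2, 7, 10, 10)

    def test_zeroed_main_path_gives_projected_input(self, rng):
        block = BasicBlock(3, 5)
        for layer in block.main.layers:
            if isinstance(layer, nn.Conv2d):
                layer.weight.data[...] = 0
                layer.bias.data[...] = 0
        x = Tensor(rng.normal(size=(1, 3, 6, 6)))
        proj = nn.conv2d(x, block.proj.weight, block.proj.bias)
        assert np.allclose(block(x).data, proj.data)

    def test_gradients_reach_projection_and_main_path(self, rng):
        block = BasicBlock(2, 4)
        x = Tensor(rng.normal(size=(1, 2, 8, 8)), requires_grad=True)
        (block(x) ** 2).sum().backward()
        for name, p in block.named_parameters():
            if p.data.size:
                assert p.grad is not None and np.isfinite(p.grad).all(), name
        assert np.abs(block.proj.weight.grad).max() > 0
        assert np.abs(block.main.layers[0].weight.grad).max() > 0


class TestAttentionBlocks:
    def test_encoder_shape_and_determinism(self, rng):
        enc = FastMHSAEncoder(8, heads=2, reduced_size=4)
        x = Tensor(rng.normal(size=(1, 8, 12, 12)))
        y1, y2 = enc(x), enc(x)
        assert y1.shape == x.shape
        assert np.array_equal(y1.data, y2.data)

    def test_encoder_gradient_reaches_every_parameter(self, rng):
        enc = FastMHSAEncoder(4, heads=2, reduced_size=2)
        x = Tensor(rng.normal(size=(1, 4, 8, 8)), requires_grad=True)
        (enc(x) ** 2).sum().backward()
        for name, p in enc.named_parameters():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name

    def test_decoder_output_on_skip_grid(self, rng):
        dec = FastMHSADecoder(8, 16, heads=2, reduced_size=4)
        hi = Tensor(rng.normal(size=(1, 8, 12, 12)))
        lo = Tensor(rng.normal(size=(1, 16, 6, 6)))
        assert dec(hi, lo).shape == (1, 8, 12, 12)

    def test_decoder_equal_grids_degenerate_case(self, rng):
        dec = FastMHSADecoder(6, 6, heads=2, reduced_size=3)
        hi = Tensor(rng.normal(size=(1, 6, 6, 6)))
        lo = Tensor(rng.normal(size=(1, 6, 6, 6)))
        assert dec(hi, lo).shape == (1, 6, 6, 6)

    def test_decoder_gradients_reach_both_inputs(self, rng):
        dec = FastMHSADecoder(4, 8, heads=2, reduced_size=2)
        hi = Tensor(rng.normal(size=(1, 4, 8, 8)), requires_grad=True)
        lo = Tensor(rng.normal(size=(1, 8, 4, 4)), requires_grad=True)
        (dec(hi, lo) ** 2).sum().backward()
        assert hi.grad is not None and np.abs(hi.grad).max() > 0
        assert lo.grad is not None and np.abs(lo.grad).max() > 0

    def test_incompatible_grids_rejected(self, rng):
        dec = FastMHSADecoder(4, 4, heads=2)
        hi = Tensor(rng.normal(size=(1, 4, 9, 9)))
        lo = Tensor(rng.normal(size=(1, 4, 6, 6)))
        with pytest.raises(ValueError, match="incompatible"):
            dec(hi, lo)


class TestVesselTransformer:
    def test_encoder_shape_and_eval_determinism(self, rng):
        vt = VesselTransformerEncoder(8, heads=2, reduced_size=4, n_experts=2)
        vt.eval()
        x = Tensor(rng.normal(size=(1, 8, 8, 8)))
        with no_grad():
            y1, y2 = vt(x), vt(x)
        assert y1.shape == x.shape
        assert np.array_equal(y1.data, y2.data)

    def test_decoder_requires_skip(self, rng):
        vt = VesselTransformerDecoder(4, 8, heads=2, reduced_size=2, n_experts=2)
        with pytest.raises(TypeError):
            vt(Tensor(rng.normal(size=(1, 4, 8, 8))))  # missing x_lo

    def test_parameter_count_linear_in_mlp_ratio(self):
        def mlp_params(ratio):
            vt = VesselTransformerEncoder(8, heads=2, mlp_ratio=ratio, n_experts=2)
            return sum(p.data.size for _, p in vt.mlp.named_parameters())

        p2, p4 = mlp_params(2), mlp_params(4)
        # hidden width doubles -> MLP weights double (bias adds sublinearly)
        assert p4 == pytest.approx(2 * p2, rel=0.1)
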