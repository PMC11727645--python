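"""Building blocks of the segmentation network.

* :func:`fast_attention` — scaled dot-product attention against keys and
  values that were spatially sub-sampled to k = h*w << n tokens, dropping
  the cost from O(n^2 d) to O(n k d).  Feature maps of natural images are
  locally redundant, so pooling K and V loses little.
* :class:`FastMHSAEncoder` / :class:`FastMHSADecoder` — multi-head wrappers:
  a depthwise-separable (or deformable, see below) input convolution, a 1x1
  Q/K/V projection, per-head fast attention on the token grid, and a 3x3
  depthwise-separable output refinement.  The decoder variant queries from
  the high-resolution skip stream and takes keys/values from the skip and
  upsampled decoder streams combined.
* :class:`VDConv` — vessel dynamic convolution: a small head predicts a
  tanh-bounded offset field for the K = 9 kernel taps (deformable sampling
  with bilinear interpolation), N expert kernels convolve the sampled
  features, and a softmax-gated per-image weight vector fuses the expert
  outputs as a convex combination.
* :class:`MSF` — multi-scale fusion: parallel 1x1, 3x3, and dilated (2, 3)
  3x3 branches, BN + LeakyReLU each, channel concatenation, 1x1 compression
  and a residual connection.
* :class:`BasicBlock` and the :class:`VesselTransformerEncoder` /
  :class:`VesselTransformerDecoder` wrappers used by the U-shaped assembly.

All blocks preserve spatial dimensions; resolution changes live in the
network assembly (:mod:`vdmnet.model`).
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concat, leaky_relu, matmul, softmax, tanh

__all__ = [
    "fast_attention",
    "subsample_kv",
    "fit_pool_size",
    "OffsetPredictor",
    "deformable_conv",
    "ExpertWeights",
    "VDConv",
    "FastMHSAEncoder",
    "FastMHSADecoder",
    "MSF",
    "BasicBlock",
    "VesselTransformerEncoder",
    "VesselTransformerDecoder",
]


# ---------------------------------------------------------------------------
# fast attention


def fast_attention(q, k_bar, v_bar) -> Tensor:
    """softmax(Q K̄ᵀ / sqrt(d)) V̄ over the trailing two axes.

    ``q``: (..., n, d); ``k_bar``, ``v_bar``: (..., k, d).  With k = n and
    unpooled keys/values this is exactly full self-attention.
    """
    q, k_bar, v_bar = as_tensor(q), as_tensor(k_bar), as_tensor(v_bar)
    d = q.shape[-1]
    if k_bar.shape[-1] != d or v_bar.shape[-2] != k_bar.shape[-2]:
        raise ValueError(
            f"inconsistent attention shapes q{q.shape} k{k_bar.shape} v{v_bar.shape}")
    scores = matmul(q, k_bar.transpose(*range(k_bar.ndim - 2), k_bar.ndim - 1, k_bar.ndim - 2))
    p_bar = softmax(scores * (1.0 / math.sqrt(d)), axis=-1)
    return matmul(p_bar, v_bar)


def fit_pool_size(size: int, target: int) -> int:
    """Largest divisor of ``size`` that is <= ``target`` (pooling factor fit)."""
    for cand in range(min(target, size), 0, -1):
        if size % cand == 0:
            return cand
    return 1


def subsample_kv(k, v, hw: tuple[int, int], reduced_hw: tuple[int, int]):
    """Average-pool token sequences (B, n, d) on their H x W grid.

    ``n`` must equal ``H*W`` (row-major tokens); returns (B, k, d) sequences
    with k = h*w.  ``reduced_hw = hw`` is the identity.
    """
    k, v = as_tensor(k), as_tensor(v)
    h, w = hw
    rh, rw = reduced_hw
    if rh > h or rw > w:
        raise ValueError(f"reduced size {reduced_hw} exceeds grid {hw}")

    def pool(tokens):
        b, n, d = tokens.shape
        if n != h * w:
            raise ValueError(f"token count {n} != grid {h}x{w}")
        maps = tokens.transpose(0, 2, 1).reshape(b, d, h, w)
        pooled = nn.avg_pool_to(maps, (rh, rw))
        return pooled.reshape(b, d, rh * rw).transpose(0, 2, 1)

    return pool(k), pool(v)


# ---------------------------------------------------------------------------
# vessel dynamic convolution


class OffsetPredictor(nn.Module):
    """Offset head: O = tanh(GN(Conv_offset(x))) in [-1, 1], (N, 2K, H, W).

    Channel 2k / 2k+1 hold the (y, x) offset of kernel tap k.  Group
    normalisation uses the largest group count <= ``gn_groups`` dividing the
    2K offset channels (2K = 18 is not divisible by the conventional 8, so
    6 groups are used at the default K = 9).
    """

    def __init__(self, in_channels: int, k_positions: int = 9, gn_groups: int = 8):
        super().__init__()
        if k_positions < 1:
            raise ValueError("k_positions must be >= 1")
        self.k_positions = k_positions
        out = 2 * k_positions
        self.conv = nn.Conv2d(in_channels, out, 3, padding=1)
        self.norm = nn.GroupNorm(fit_pool_size(out, gn_groups), out)

    def forward(self, x) -> Tensor:
        return tanh(self.norm(self.conv(x)))


def deformable_conv(x, offsets, weight, bias=None, dilation: int = 1,
                    offset_scale: float = 1.0, groups: int = 1) -> Tensor:
    """Deformable 3x3 convolution: Y(i,j) = sum_k W_k * X(i+O_y_k, j+O_x_k).

    Sampling positions are the regular (dilated) 3x3 grid displaced by
    ``offset_scale * offsets``; fractional positions are bilinearly
    interpolated with zero padding outside the image.  With a zero offset
    field this reduces exactly to the standard (grouped) convolution with
    the same ``weight``.
    """
    weight = as_tensor(weight)
    cout, cg, kh, kw = weight.shape
    if (kh, kw) != (3, 3):
        raise ValueError("deformable_conv implements 3x3 kernels")
    sampled = nn.deform_sample(x, offsets, kernel_size=3, dilation=dilation,
                               offset_scale=offset_scale)
    w_flat = weight.reshape(cout, cg * 9, 1, 1)
    return nn.conv2d(sampled, w_flat, bias, groups=groups)


class ExpertWeights(nn.Module):
    """Per-image expert gate: global average pool -> 1x1 conv -> softmax.

    Returns (B, N, 1, 1) nonnegative weights summing to 1 over the expert
    axis for every image.
    """

    def __init__(self, in_channels: int, n_experts: int):
        super().__init__()
        if n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        self.n_experts = n_experts
        self.gate = nn.Conv2d(in_channels, n_experts, 1)

    def forward(self, x) -> Tensor:
        _, _, h, w = x.shape
        logits = self.gate(nn.avg_pool_to(x, (1, 1)))
        return softmax(logits, axis=1)


class VDConv(nn.Module):
    """Vessel dynamic convolution: offsets -> expert deformable convs -> fusion.

    One offset field is shared by all experts; each expert owns a distinct
    3x3 kernel bank applied as a grouped convolution over the deformably
    sampled features, and the outputs are fused as Z = sum_n alpha_n * Y_n
    with input-dependent softmax weights alpha.
    """

    def __init__(self, in_channels: int, out_channels: int, n_experts: int = 4,
                 groups: int = 1, dilation: int = 1, offset_scale: float = 2.0,
                 gn_groups: int = 8):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}")
        self.groups, self.dilation, self.offset_scale = groups, dilation, offset_scale
        self.n_experts = n_experts
        self.offset_head = OffsetPredictor(in_channels, 9, gn_groups)
        self.expert_gate = ExpertWeights(in_channels, n_experts)
        cg = in_channels // groups
        fan_in = cg * 9
        self.expert_kernels = nn.Parameter(np.stack([
            nn._kaiming_uniform((out_channels, cg, 3, 3), fan_in)
            for _ in range(n_experts)
        ]))
        self.bias = nn.Parameter(np.zeros(out_channels))

    def forward(self, x, offsets: Tensor | None = None) -> Tensor:
        x = as_tensor(x)
        if offsets is None:
            offsets = self.offset_head(x)
        alpha = self.expert_gate(x)
        sampled = nn.deform_sample(x, offsets, kernel_size=3, dilation=self.dilation,
                                   offset_scale=self.offset_scale)
        cout = self.expert_kernels.shape[1]
        cg = self.expert_kernels.shape[2]
        z = None
        for n in range(self.n_experts):
            w_flat = self.expert_kernels[n].reshape(cout, cg * 9, 1, 1)
            y_n = nn.conv2d(sampled, w_flat, groups=self.groups)
            term = alpha[:, n: n + 1] * y_n
            z = term if z is None else z + term
        return z + self.bias.reshape(1, -1, 1, 1)


# ---------------------------------------------------------------------------
# fast multi-head self-attention blocks


def _tokens_from_map(x, heads: int):
    b, c, h, w = x.shape
    d = c // heads
    return x.reshape(b, heads, d, h * w).transpose(0, 1, 3, 2)  # (B, heads, n, d)


def _map_from_tokens(tokens, c: int, h: int, w: int):
    b = tokens.shape[0]
    return tokens.transpose(0, 1, 3, 2).reshape(b, c, h, w)


class FastMHSAEncoder(nn.Module):
    """Encoder-side fast multi-head self-attention on a feature map.

    input conv -> 1x1 Q/K/V projection -> spatial sub-sampling of K, V to at
    most ``reduced_size``^2 tokens -> per-head fast attention -> 3x3
    depthwise-separable refinement.  ``input_conv`` defaults to a 3x3
    depthwise-separable convolution and is replaced by a :class:`VDConv`
    inside the vessel transformer blocks.
    """

    def __init__(self, channels: int, heads: int = 4, reduced_size: int = 8,
                 input_conv: nn.Module | None = None):
        super().__init__()
        if channels % heads:
            raise ValueError(f"channels {channels} not divisible by heads {heads}")
        self.heads, self.reduced_size = heads, reduced_size
        self.input_conv = input_conv or nn.DepthwiseSeparableConv(channels, channels)
        self.qkv = nn.Conv2d(channels, 3 * channels, 1)
        self.out_conv = nn.DepthwiseSeparableConv(channels, channels)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        b, c, h, w = x.shape
        f = self.input_conv(x)
        qkv = self.qkv(f)
        q_map, k_map, v_map = qkv[:, :c], qkv[:, c: 2 * c], qkv[:, 2 * c:]
        rh, rw = fit_pool_size(h, self.reduced_size), fit_pool_size(w, self.reduced_size)
        k_map = nn.avg_pool_to(k_map, (rh, rw))
        v_map = nn.avg_pool_to(v_map, (rh, rw))
        q = _tokens_from_map(q_map, self.heads)
        k = _tokens_from_map(k_map, self.heads)
        v = _tokens_from_map(v_map, self.heads)
        out = _map_from_tokens(fast_attention(q, k, v), c, h, w)
        return self.out_conv(out)


class FastMHSADecoder(nn.Module):
    """Decoder-side fast attention over skip (high-res) and decoder (low-res)
    streams.

    The low-resolution stream is nearest-upsampled to the skip grid and the
    two are concatenated and passed through the input convolution; queries
    come from the high-resolution stream alone, keys/values from the
    combined features.  Output lives on the skip grid with the skip's
    channel count.
    """

    def __init__(self, hi_channels: int, lo_channels: int, heads: int = 4,
                 reduced_size: int = 8, input_conv: nn.Module | None = None):
        super().__init__()
        if hi_channels % heads:
            raise ValueError(f"channels {hi_channels} not divisible by heads {heads}")
        self.heads, self.reduced_size = heads, reduced_size
        self.input_conv = input_conv or nn.DepthwiseSeparableConv(
            hi_channels + lo_channels, hi_channels)
        self.q_proj = nn.Conv2d(hi_channels, hi_channels, 1)
        self.kv_proj = nn.Conv2d(hi_channels, 2 * hi_channels, 1)
        self.out_conv = nn.DepthwiseSeparableConv(hi_channels, hi_channels)

    def forward(self, x_hi, x_lo) -> Tensor:
        x_hi, x_lo = as_tensor(x_hi), as_tensor(x_lo)
        b, c, h, w = x_hi.shape
        lh, lw = x_lo.shape[2:]
        while (lh, lw) != (h, w):
            if lh > h or lw > w or h % lh or w % lw:
                raise ValueError(
                    f"decoder stream {x_lo.shape} incompatible with skip grid {h}x{w}")
            x_lo = nn.upsample_nearest2x(x_lo)
            lh, lw = x_lo.shape[2:]
        combined = self.input_conv(concat([x_hi, x_lo], axis=1))
        kv = self.kv_proj(combined)
        k_map, v_map = kv[:, :c], kv[:, c:]
        rh, rw = fit_pool_size(h, self.reduced_size), fit_pool_size(w, self.reduced_size)
        k_map = nn.avg_pool_to(k_map, (rh, rw))
        v_map = nn.avg_pool_to(v_map, (rh, rw))
        q = _tokens_from_map(self.q_proj(x_hi), self.heads)
        k = _tokens_from_map(k_map, self.heads)
        v = _tokens_from_map(v_map, self.heads)
        out = _map_from_tokens(fast_attention(q, k, v), c, h, w)
        return self.out_conv(out)


# ---------------------------------------------------------------------------
# multi-scale fusion and basic block


class MSF(nn.Module):
    """Multi-scale fusion: 1x1, 3x3, and dilated-(2,3) 3x3 branches with BN
    and LeakyReLU, concatenated, compressed by 1x1 and added to the input."""

    def __init__(self, channels: int, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope
        specs = [(1, 0, 1), (3, 1, 1), (3, 2, 2), (3, 3, 3)]
        self.branches = [
            nn.Sequential(
                nn.Conv2d(channels, channels, k, padding=p, dilation=d),
                nn.BatchNorm2d(channels),
                nn.LeakyReLU(negative_slope),
            )
            for k, p, d in specs
        ]
        self.compress = nn.Conv2d(4 * channels, channels, 1)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        fused = concat([branch(x) for branch in self.branches], axis=1)
        return x + self.compress(fused)


class BasicBlock(nn.Module):
    """(3x3 conv -> BN -> LeakyReLU) x2 plus a residual connection; the
    residual uses a 1x1 projection when channel counts differ."""

    def __init__(self, in_channels: int, out_channels: int, negative_slope: float = 0.01):
        super().__init__()
        self.main = nn.Sequential(
            nn.Conv2d(in_channels, out_channels, 3, padding=1),
            nn.BatchNorm2d(out_channels),
            nn.LeakyReLU(negative_slope),
            nn.Conv2d(out_channels, out_channels, 3, padding=1),
            nn.BatchNorm2d(out_channels),
            nn.LeakyReLU(negative_slope),
        )
        self.proj = (nn.Identity() if in_channels == out_channels
                     else nn.Conv2d(in_channels, out_channels, 1))

    def forward(self, x) -> Tensor:
        return self.proj(x) + self.main(x)


# ---------------------------------------------------------------------------
# vessel transformer wrappers


class _MLP(nn.Module):
    def __init__(self, channels: int, ratio: int = 4, negative_slope: float = 0.01):
        super().__init__()
        hidden = channels * ratio
        self.net = nn.Sequential(
            nn.Conv2d(channels, hidden, 1),
            nn.LeakyReLU(negative_slope),
            nn.Conv2d(hidden, channels, 1),
        )

    def forward(self, x):
        return self.net(x)


class VesselTransformerEncoder(nn.Module):
    """BN -> FastMHSA (with a VDConv input stage) -> LeakyReLU -> MLP, with a
    residual connection around each sub-block."""

    def __init__(self, channels: int, heads: int = 4, reduced_size: int = 8,
                 n_experts: int = 4, offset_scale: float = 2.0, mlp_ratio: int = 4,
                 negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope
        self.norm1 = nn.BatchNorm2d(channels)
        self.attn = FastMHSAEncoder(
            channels, heads, reduced_size,
            input_conv=VDConv(channels, channels, n_experts=n_experts,
                              offset_scale=offset_scale))
        self.norm2 = nn.BatchNorm2d(channels)
        self.mlp = _MLP(channels, mlp_ratio, negative_slope)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        a = x + self.attn(self.norm1(x))
        return a + self.mlp(leaky_relu(self.norm2(a), self.negative_slope))


class VesselTransformerDecoder(nn.Module):
    """Decoder counterpart: fuses the skip stream with the upsampled decoder
    stream through decoder-side fast attention, then applies the MLP."""

    def __init__(self, hi_channels: int, lo_channels: int, heads: int = 4,
                 reduced_size: int = 8, n_experts: int = 4, offset_scale: float = 2.0,
                 mlp_ratio: int = 4, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope
        self.norm_hi = nn.BatchNorm2d(hi_channels)
        self.norm_lo = nn.BatchNorm2d(lo_channels)
        self.attn = FastMHSADecoder(
            hi_channels, lo_channels, heads, reduced_size,
            input_conv=VDConv(hi_channels + lo_channels, hi_channels,
                              n_experts=n_experts, offset_scale=offset_scale))
        self.norm2 = nn.BatchNorm2d(hi_channels)
        self.mlp = _MLP(hi_channels, mlp_ratio, negative_slope)

    def forward(self, x_hi, x_lo) -> Tensor:
        x_hi, x_lo = as_tensor(x_hi), as_tensor(x_lo)
        a = x_hi + self.attn(self.norm_hi(x_hi), self.norm_lo(x_lo))
        return a + self.mlp(leaky_relu(self.norm2(a), self.negative_slope))
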