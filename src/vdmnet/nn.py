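"""Neural-network layers on top of :mod:`vdmnet.autodiff`.

Structured primitives (convolution, transposed convolution, pooling,
bilinear deformable sampling) are implemented as single tape nodes with
hand-written vector–Jacobian products; everything else (normalisation,
activations, attention) is composed from elementwise autodiff ops.

Convolutions use an im2col layout built from nine strided slices, so both
the forward and backward passes reduce to batched matrix products.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, leaky_relu, sqrt

_init_rng = np.random.default_rng(0)


def seed_init(seed: int) -> None:
    """Seed the generator used for parameter initialisation.

    Layer parameters are drawn from a module-level stream, so building the
    same architecture after the same ``seed_init`` call yields bit-identical
    weights.
    """
    global _init_rng
    _init_rng = np.random.default_rng(int(seed))


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: attribute-scanned parameters, train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data[...] = value
            else:
                self._assign_buffer(name, value)

    def _assign_buffer(self, dotted: str, value: np.ndarray) -> None:
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        target = getattr(obj, parts[-1])
        target[...] = value


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x):
        return leaky_relu(x, self.negative_slope)


# ---------------------------------------------------------------------------
# convolution primitive


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, dilation: int,
            ho: int, wo: int) -> np.ndarray:
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[
                :, :,
                i * dilation: i * dilation + (ho - 1) * stride + 1: stride,
                j * dilation: j * dilation + (wo - 1) * stride + 1: stride,
            ]
    return cols


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           dilation: int = 1, groups: int = 1) -> Tensor:
    """2D convolution (cross-correlation) with zero padding.

    ``x``: (N, Cin, H, W); ``weight``: (Cout, Cin/groups, kh, kw);
    ``bias``: (Cout,) or None.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    xd, wd = x.data, weight.data
    n, cin, h, w = xd.shape
    cout, cg, kh, kw = wd.shape
    if cin != cg * groups:
        raise ValueError(f"channels {cin} incompatible with groups {groups} x {cg}")
    ho = (h + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    wo = (w + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, stride, dilation, ho, wo)
    cols_g = cols.reshape(n, groups, cg * kh * kw, ho * wo)
    wg = wd.reshape(groups, cout // groups, cg * kh * kw)
    out = np.matmul(wg[None], cols_g).reshape(n, cout, ho, wo)

    parents = (x, weight)
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data.reshape(1, cout, 1, 1)
        parents = (x, weight, bias)

    def vjp(g):
        gg = g.reshape(n, groups, cout // groups, ho * wo)
        dw = np.matmul(gg, cols_g.transpose(0, 1, 3, 2)).sum(axis=0).reshape(wd.shape)
        dcols = np.matmul(np.swapaxes(wg, -1, -2)[None], gg)
        dcols = dcols.reshape(n, cin, kh, kw, ho, wo)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[
                    :, :,
                    i * dilation: i * dilation + (ho - 1) * stride + 1: stride,
                    j * dilation: j * dilation + (wo - 1) * stride + 1: stride,
                ] += dcols[:, :, i, j]
        dx = dxp[:, :, padding: padding + h, padding: padding + w]
        grads = [dx, dw]
        if len(parents) == 3:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor._op(out, parents, vjp)


def conv_transpose2d_2x(x, weight, bias=None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (non-overlapping upsample).

    ``weight``: (Cin, Cout, 2, 2).  Doubles the spatial resolution.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    xd, wd = x.data, weight.data
    n, cin, h, w = xd.shape
    _, cout, _, _ = wd.shape
    out = np.zeros((n, cout, 2 * h, 2 * w), dtype=xd.dtype)
    for k in range(2):
        for l in range(2):
            out[:, :, k::2, l::2] = np.tensordot(xd, wd[:, :, k, l], axes=([1], [0])).transpose(0, 3, 1, 2)
    parents = (x, weight)
    if bias is not None:
        bias = as_tensor(bias)
        out = out + bias.data.reshape(1, cout, 1, 1)
        parents = (x, weight, bias)

    def vjp(g):
        dx = np.zeros_like(xd)
        dw = np.zeros_like(wd)
        for k in range(2):
            for l in range(2):
                gkl = g[:, :, k::2, l::2]
                dx += np.tensordot(gkl, wd[:, :, k, l], axes=([1], [1])).transpose(0, 3, 1, 2)
                dw[:, :, k, l] = np.tensordot(xd, gkl, axes=([0, 2, 3], [0, 2, 3]))
        grads = [dx, dw]
        if len(parents) == 3:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    return Tensor._op(out, parents, vjp)


def max_pool2x(x) -> Tensor:
    """2x2 max pooling, stride 2; ties resolve to the first maximum."""
    x = as_tensor(x)
    xd = x.data
    n, c, h, w = xd.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x needs even spatial dims, got {h}x{w}")
    blocks = xd.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (dx.reshape(xd.shape),)

    return Tensor._op(out, (x,), vjp)


def avg_pool_to(x, out_hw: tuple[int, int]) -> Tensor:
    """Average-pool the spatial grid down to ``out_hw`` (block means).

    The target size must divide the input size evenly; pooling to the input
    size is the identity.
    """
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    oh, ow = out_hw
    if oh > h or ow > w:
        raise ValueError(f"cannot pool {h}x{w} up to {oh}x{ow}")
    if h % oh or w % ow:
        raise ValueError(f"pool target {oh}x{ow} must divide input {h}x{w}")
    fh, fw = h // oh, w // ow
    out = x.data.reshape(n, c, oh, fh, ow, fw).mean(axis=(3, 5))
    scale = 1.0 / (fh * fw)

    def vjp(g):
        gg = np.broadcast_to(g[:, :, :, None, :, None] * scale, (n, c, oh, fh, ow, fw))
        return (gg.reshape(n, c, h, w).copy(),)

    return Tensor._op(out, (x,), vjp)


def upsample_nearest2x(x) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def vjp(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return Tensor._op(out, (x,), vjp)


# ---------------------------------------------------------------------------
# deformable bilinear sampling


def deform_sample(x, offsets, kernel_size: int = 3, dilation: int = 1,
                  offset_scale: float = 1.0) -> Tensor:
    """Sample ``x`` at the K = kernel_size**2 displaced kernel positions.

    For each output location (i, j) and kernel tap k the sampling point is
    ``(i + base_y_k + s*O_y_k, j + base_x_k + s*O_x_k)`` where the base grid
    is the regular dilated kernel, O is the predicted offset field
    (N, 2K, H, W) with the (y, x) pair of tap k in channels (2k, 2k+1), and
    ``s = offset_scale`` converts normalised offsets to pixels.  Values are
    bilinearly interpolated with zeros outside the image.

    Returns (N, C*K, H, W): tap k of channel c lands at channel ``c*K + k``,
    so a subsequent 1x1 grouped convolution implements the deformable
    convolution's weighted sum over taps.
    """
    x, offsets = as_tensor(x), as_tensor(offsets)
    xd, od = x.data, offsets.data
    n, c, h, w = xd.shape
    k_total = kernel_size * kernel_size
    if od.shape != (n, 2 * k_total, h, w):
        raise ValueError(f"offset field shape {od.shape} != {(n, 2 * k_total, h, w)}")

    half = (kernel_size - 1) / 2.0
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    idx_n = np.arange(n)[:, None, None]
    x_nhwc = xd.transpose(0, 2, 3, 1)

    out = np.empty((n, c, k_total, h, w), dtype=xd.dtype)
    cache = []
    for k in range(k_total):
        ki, kj = divmod(k, kernel_size)
        yy = ii[None] + (ki - half) * dilation + offset_scale * od[:, 2 * k]
        xx = jj[None] + (kj - half) * dilation + offset_scale * od[:, 2 * k + 1]
        y0 = np.floor(yy).astype(np.int64)
        x0 = np.floor(xx).astype(np.int64)
        wy = yy - y0
        wx = xx - x0
        corners = []
        for dy in (0, 1):
            for dx in (0, 1):
                yi, xi = y0 + dy, x0 + dx
                valid = (yi >= 0) & (yi < h) & (xi >= 0) & (xi < w)
                vals = x_nhwc[idx_n, np.clip(yi, 0, h - 1), np.clip(xi, 0, w - 1)]
                vals = vals * valid[..., None]
                corners.append((vals, valid, yi, xi))
        v00, v01, v10, v11 = (cn[0] for cn in corners)
        top = v00 * (1 - wx)[..., None] + v01 * wx[..., None]
        bot = v10 * (1 - wx)[..., None] + v11 * wx[..., None]
        out[:, :, k] = (top * (1 - wy)[..., None] + bot * wy[..., None]).transpose(0, 3, 1, 2)
        cache.append((corners, wy, wx))

    out = out.reshape(n, c * k_total, h, w)

    def vjp(g):
        gk = g.reshape(n, c, k_total, h, w)
        dx_nhwc = np.zeros_like(x_nhwc)
        doff = np.zeros_like(od)
        for k in range(k_total):
            corners, wy, wx = cache[k]
            gnhwc = gk[:, :, k].transpose(0, 2, 3, 1)
            (v00, m00, y00, x00), (v01, m01, y01, x01), \
                (v10, m10, y10, x10), (v11, m11, y11, x11) = corners
            w00 = (1 - wy) * (1 - wx)
            w01 = (1 - wy) * wx
            w10 = wy * (1 - wx)
            w11 = wy * wx
            for (vals, valid, yi, xi), cw in zip(corners, (w00, w01, w10, w11)):
                contrib = gnhwc * (cw * valid)[..., None]
                np.add.at(dx_nhwc, (idx_n, np.clip(yi, 0, h - 1), np.clip(xi, 0, w - 1)), contrib)
            gsum = gnhwc  # (n, h, w, c)
            dval_dy = (v10 - v00) * (1 - wx)[..., None] + (v11 - v01) * wx[..., None]
            dval_dx = (v01 - v00) * (1 - wy)[..., None] + (v11 - v10) * wy[..., None]
            doff[:, 2 * k] = (gsum * dval_dy).sum(axis=-1) * offset_scale
            doff[:, 2 * k + 1] = (gsum * dval_dx).sum(axis=-1) * offset_scale
        return dx_nhwc.transpose(0, 3, 1, 2), doff

    return Tensor._op(out, (x, offsets), vjp)


# ---------------------------------------------------------------------------
# layers


def _kaiming_uniform(shape, fan_in, slope=0.01):
    gain = np.sqrt(2.0 / (1.0 + slope**2))
    bound = gain * np.sqrt(3.0 / fan_in)
    return _init_rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, dilation=1, groups=1, bias=True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}")
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(_kaiming_uniform(
            (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.dilation, self.groups)


class ConvTranspose2x(Module):
    """Kernel-2 stride-2 transposed convolution (the decoder's Up-Conv)."""

    def __init__(self, in_channels, out_channels, bias=True):
        super().__init__()
        self.weight = Parameter(_kaiming_uniform(
            (in_channels, out_channels, 2, 2), in_channels * 4))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return conv_transpose2d_2x(x, self.weight, self.bias)


class DepthwiseSeparableConv(Module):
    """3x3 depthwise convolution followed by a 1x1 pointwise convolution."""

    def __init__(self, in_channels, out_channels, kernel_size=3):
        super().__init__()
        self.depthwise = Conv2d(in_channels, in_channels, kernel_size,
                                padding=kernel_size // 2, groups=in_channels)
        self.pointwise = Conv2d(in_channels, out_channels, 1)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    The training recipe uses batch size 1, where batch statistics are the
    per-image statistics; running averages (momentum 0.1) are used in eval
    mode.
    """

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean *= 1 - m
            self.running_mean += m * mu.data.ravel()
            self.running_var *= 1 - m
            self.running_var += m * var.data.ravel()
            xhat = centered / sqrt(var + self.eps)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class GroupNorm(Module):
    def __init__(self, num_groups, num_channels, eps=1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError(f"{num_channels} channels not divisible by {num_groups} groups")
        self.num_groups, self.eps = num_groups, eps
        self.gamma = Parameter(np.ones(num_channels))
        self.beta = Parameter(np.zeros(num_channels))

    def forward(self, x):
        n, c, h, w = x.shape
        g = self.num_groups
        xg = x.reshape(n, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        centered = xg - mu
        var = (centered * centered).mean(axis=2, keepdims=True)
        xhat = (centered / sqrt(var + self.eps)).reshape(n, c, h, w)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        self.weight = Parameter(_kaiming_uniform((in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
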