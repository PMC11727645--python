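"""U-shaped assembly of the vessel segmentation network.

Encoder levels run [BasicBlock -> (VesselTransformerEncoder at the deepest
levels) -> (MSF) -> skip -> MaxPool]; a BasicBlock bottleneck sits below.
The decoder mirrors the encoder: at transformer levels the skip and the
deeper decoder stream are fused by a VesselTransformerDecoder (which
upsamples internally through its attention stage); elsewhere a kernel-2
stride-2 transposed convolution upsamples, the skip is concatenated, and a
BasicBlock fuses.  A 1x1 convolution plus sigmoid produces the vessel
probability map.

The published architecture figure leaves level counts, channel widths and
head counts open; the defaults here (4 levels, base 32 channels doubling
per level, transformers at the 2 deepest levels, 4 heads, 4 experts) are
one concrete instantiation, and every choice is a config knob.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concat, no_grad, sigmoid
from .blocks import (
    MSF,
    BasicBlock,
    VesselTransformerDecoder,
    VesselTransformerEncoder,
)

__all__ = ["ModelConfig", "VDMNet", "build_vdmnet", "predict"]


@dataclass
class ModelConfig:
    """Architecture hyper-parameters; all are free knobs of the assembly."""

    levels: int = 4
    base_channels: int = 32
    transformer_levels: int = 2
    heads: int = 4
    experts: int = 4
    offset_scale: float = 2.0
    msf_enabled: bool = True
    reduced_size: int = 8  # K/V token grid is at most reduced_size^2
    mlp_ratio: int = 4
    negative_slope: float = 0.01
    in_channels: int = 1
    init_seed: int = 0

    def validate(self) -> None:
        if self.levels < 1:
            raise ValueError("config key 'levels' must be >= 1")
        if not 0 <= self.transformer_levels <= self.levels:
            raise ValueError(
                "config key 'transformer_levels' must lie in [0, levels]")
        if self.base_channels < 1:
            raise ValueError("config key 'base_channels' must be >= 1")
        for lvl in range(self.levels):
            ch = self.base_channels * 2**lvl
            if lvl >= self.levels - self.transformer_levels and ch % self.heads:
                raise ValueError(
                    f"config key 'heads': {ch} channels at level {lvl} not divisible "
                    f"by heads={self.heads}")


class VDMNet(nn.Module):
    """The full encoder/decoder segmentation network."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        cfg = cfg or ModelConfig()
        cfg.validate()
        nn.seed_init(cfg.init_seed)
        self.cfg = cfg
        ch = [cfg.base_channels * 2**i for i in range(cfg.levels)]
        bottleneck_ch = cfg.base_channels * 2**cfg.levels
        is_tf = [i >= cfg.levels - cfg.transformer_levels for i in range(cfg.levels)]

        self.enc_blocks = []
        self.enc_tf = []
        self.enc_msf = []
        prev = cfg.in_channels
        for i in range(cfg.levels):
            self.enc_blocks.append(BasicBlock(prev, ch[i], cfg.negative_slope))
            self.enc_tf.append(
                VesselTransformerEncoder(
                    ch[i], cfg.heads, cfg.reduced_size, cfg.experts,
                    cfg.offset_scale, cfg.mlp_ratio, cfg.negative_slope)
                if is_tf[i] else nn.Identity())
            self.enc_msf.append(MSF(ch[i], cfg.negative_slope)
                                if cfg.msf_enabled else nn.Identity())
            prev = ch[i]

        self.bottleneck = BasicBlock(ch[-1], bottleneck_ch, cfg.negative_slope)

        self.dec_up = []
        self.dec_fuse = []
        deep = bottleneck_ch
        for i in reversed(range(cfg.levels)):
            if is_tf[i]:
                self.dec_up.append(nn.Identity())
                self.dec_fuse.append(VesselTransformerDecoder(
                    ch[i], deep, cfg.heads, cfg.reduced_size, cfg.experts,
                    cfg.offset_scale, cfg.mlp_ratio, cfg.negative_slope))
            else:
                self.dec_up.append(nn.ConvTranspose2x(deep, ch[i]))
                self.dec_fuse.append(BasicBlock(2 * ch[i], ch[i], cfg.negative_slope))
            deep = ch[i]

        self.head = nn.Conv2d(ch[0], 1, 1)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        h, w = x.shape[2:]
        factor = 2 ** self.cfg.levels
        if h % factor or w % factor:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^levels={factor}; use predict() "
                "for automatic padding")
        skips = []
        for block, tf, msf in zip(self.enc_blocks, self.enc_tf, self.enc_msf):
            x = msf(tf(block(x)))
            skips.append(x)
            x = nn.max_pool2x(x)
        x = self.bottleneck(x)
        for up, fuse, skip in zip(self.dec_up, self.dec_fuse, reversed(skips)):
            if isinstance(fuse, VesselTransformerDecoder):
                x = fuse(skip, x)
            else:
                x = fuse(concat([skip, up(x)], axis=1))
        return sigmoid(self.head(x))


def build_vdmnet(cfg: ModelConfig | None = None) -> VDMNet:
    """Build the network from a config (invalid configs raise naming the key)."""
    return VDMNet(cfg)


def predict(model: VDMNet, image: np.ndarray, threshold: float = 0.5):
    """Segment a single [0, 1] grayscale image.

    Pads reflectively to a multiple of 2^levels, runs the network in eval
    mode without recording gradients, and crops back.  Returns
    ``(prob_map, binary_mask)`` with ``mask = prob >= threshold``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {image.shape}")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    h, w = image.shape
    factor = 2 ** model.cfg.levels
    ph = (-h) % factor
    pw = (-w) % factor
    padded = np.pad(image, ((0, ph), (0, pw)), mode="reflect")
    was_training = model.training
    model.eval()
    try:
        with no_grad():
            prob = model(padded[None, None]).data[0, 0, :h, :w]
    finally:
        model.train(was_training)
    return prob, (prob >= threshold).astype(np.uint8)
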