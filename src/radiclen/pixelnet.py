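"""Pixel-level feature extraction: backbone, FPN, SE recalibration, bases.

The path is: residual backbone stages C3-C5 (strides 8/16/32; the dense C1/C2
stages are never materialized downstream), a feature pyramid P3-P7 built
top-down from a 1x1-conv of C5 with lateral 1x1 connections and two plain
factor-2 downsamplings for P6/P7, per-level squeeze-and-excitation blocks
giving F3-F7, and a basis decoder that fuses {F3,F4,F5} into a k-channel
stride-4 basis tensor B of instance-agnostic, position-sensitive patterns.

All upsampling is bilinear with the align_corners=False convention; odd
spatial sizes are handled by ceil-mode downsampling and by upsampling to the
exact lateral partner shape.
"""

from __future__ import annotations

import numpy as np

from .conf import ModelConfig
from .nnet import (BatchNorm2d, Conv2d, ConvBNReLU, Linear, Module, Tensor,
                   bilinear_resize, downsample2)


def pad_to_stride(image: np.ndarray, stride: int = 32) -> np.ndarray:
    """Zero-pad an (N,C,H,W) array on the bottom/right to a stride multiple."""
    h, w = image.shape[-2:]
    if min(h, w) < stride:
        raise ValueError(
            f"image {h}x{w} is smaller than one stride-{stride} cell"
        )
    ph = (-h) % stride
    pw = (-w) % stride
    if ph == 0 and pw == 0:
        return image
    pad = [(0, 0)] * (image.ndim - 2) + [(0, ph), (0, pw)]
    return np.pad(image, pad)


class BasicBlock(Module):
    def __init__(self, rng, in_ch, out_ch, stride=1):
        super().__init__()
        self.c1 = Conv2d(rng, in_ch, out_ch, 3, stride=stride, bias=False)
        self.b1 = BatchNorm2d(out_ch)
        self.c2 = Conv2d(rng, out_ch, out_ch, 3, bias=False)
        self.b2 = BatchNorm2d(out_ch)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(rng, in_ch, out_ch, 1, stride=stride, bias=False)
            self.bproj = BatchNorm2d(out_ch)

    def forward(self, x):
        out = self.b2(self.c2(self.b1(self.c1(x)).relu()))
        shortcut = x if self.proj is None else self.bproj(self.proj(x))
        return (out + shortcut).relu()


class Bottleneck(Module):
    expansion = 4

    def __init__(self, rng, in_ch, mid_ch, stride=1):
        super().__init__()
        out_ch = mid_ch * self.expansion
        self.c1 = Conv2d(rng, in_ch, mid_ch, 1, bias=False)
        self.b1 = BatchNorm2d(mid_ch)
        self.c2 = Conv2d(rng, mid_ch, mid_ch, 3, stride=stride, bias=False)
        self.b2 = BatchNorm2d(mid_ch)
        self.c3 = Conv2d(rng, mid_ch, out_ch, 1, bias=False)
        self.b3 = BatchNorm2d(out_ch)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = Conv2d(rng, in_ch, out_ch, 1, stride=stride, bias=False)
            self.bproj = BatchNorm2d(out_ch)

    def forward(self, x):
        out = self.b1(self.c1(x)).relu()
        out = self.b2(self.c2(out)).relu()
        out = self.b3(self.c3(out))
        shortcut = x if self.proj is None else self.bproj(self.proj(x))
        return (out + shortcut).relu()


class Backbone(Module):
    """Residual backbone exposing {C3, C4, C5} at strides 8/16/32."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        self.profile = cfg.profile
        if cfg.profile == "tiny":
            self.stem1 = ConvBNReLU(rng, 3, 32, stride=2)
            self.stem2 = ConvBNReLU(rng, 32, 64, stride=2)
            self.stage3 = BasicBlock(rng, 64, 64, stride=2)
            self.stage4 = BasicBlock(rng, 64, 128, stride=2)
            self.stage5 = BasicBlock(rng, 128, 256, stride=2)
        else:
            self.stem1 = ConvBNReLU(rng, 3, 64, kernel=7, stride=2)
            self.stem2 = ConvBNReLU(rng, 64, 64, stride=2)
            def stage(in_ch, mid, blocks, stride):
                mods = [Bottleneck(rng, in_ch, mid, stride=stride)]
                for _ in range(blocks - 1):
                    mods.append(Bottleneck(rng, mid * 4, mid))
                return mods
            from .nnet import Sequential
            self.stage2 = Sequential(*stage(64, 64, 3, 1))
            self.stage3 = Sequential(*stage(256, 128, 4, 2))
            self.stage4 = Sequential(*stage(512, 256, 6, 2))
            self.stage5 = Sequential(*stage(1024, 512, 3, 2))

    def forward(self, x: Tensor) -> dict:
        x = self.stem2(self.stem1(x))
        if self.profile == "tiny":
            c3 = self.stage3(x)
            c4 = self.stage4(c3)
            c5 = self.stage5(c4)
        else:
            c2 = self.stage2(x)
            c3 = self.stage3(c2)
            c4 = self.stage4(c3)
            c5 = self.stage5(c4)
        return {"C3": c3, "C4": c4, "C5": c5}


class FPN(Module):
    """Top-down pyramid: P5 = 1x1(C5); P4/P3 add lateral 1x1; P6/P7 by
    plain factor-2 downsampling of the level above."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        c3, c4, c5 = cfg.backbone_channels
        ch = cfg.fpn_channels
        self.lat5 = Conv2d(rng, c5, ch, 1)
        self.lat4 = Conv2d(rng, c4, ch, 1)
        self.lat3 = Conv2d(rng, c3, ch, 1)

    def forward(self, c: dict) -> dict:
        p5 = self.lat5(c["C5"])
        h4, w4 = c["C4"].shape[-2:]
        p4 = bilinear_resize(p5, h4, w4) + self.lat4(c["C4"])
        h3, w3 = c["C3"].shape[-2:]
        p3 = bilinear_resize(p4, h3, w3) + self.lat3(c["C3"])
        p6 = downsample2(p5)
        p7 = downsample2(p6)
        return {"P3": p3, "P4": p4, "P5": p5, "P6": p6, "P7": p7}


class SEBlock(Module):
    """Squeeze-excitation: global average -> bottleneck gate -> scale."""

    def __init__(self, rng, channels: int, ratio: int = 16):
        super().__init__()
        if channels % ratio != 0:
            raise ValueError(
                f"SE ratio {ratio} does not divide channel count {channels}"
            )
        self.fc1 = Linear(rng, channels, channels // ratio, bias=False)
        self.fc2 = Linear(rng, channels // ratio, channels, bias=False)

    def forward(self, p: Tensor) -> Tensor:
        z = p.mean(axis=(2, 3))  # (N, C): squeeze
        s = self.fc2(self.fc1(z).relu()).sigmoid()  # excitation gate
        n, c = s.shape
        return p * s.reshape(n, c, 1, 1)  # scale


class BasisDecoder(Module):
    """Fuse {F3,F4,F5} into the k-channel stride-4 basis tensor B."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        ch = cfg.fpn_channels
        self.refine3 = ConvBNReLU(rng, ch, ch)
        self.refine4 = ConvBNReLU(rng, ch, ch)
        self.refine5 = ConvBNReLU(rng, ch, ch)
        from .nnet import Sequential
        self.tower = Sequential(*[ConvBNReLU(rng, ch, ch) for _ in range(cfg.n)])
        self.post = Conv2d(rng, ch, ch, 3)
        self.out = Conv2d(rng, ch, cfg.k, 1)

    def forward(self, f3: Tensor, f4: Tensor, f5: Tensor) -> Tensor:
        h, w = f3.shape[-2:]
        x = (self.refine3(f3)
             + bilinear_resize(self.refine4(f4), h, w)
             + bilinear_resize(self.refine5(f5), h, w))
        x = self.tower(x)
        x = bilinear_resize(x, 2 * h, 2 * w)
        return self.out(self.post(x).relu())


class PixelNet(Module):
    """Backbone + FPN + SE + basis decoder; returns all named feature maps."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.backbone = Backbone(rng, cfg)
        self.fpn = FPN(rng, cfg)
        for i in range(3, 8):
            setattr(self, f"se{i}", SEBlock(rng, cfg.fpn_channels, cfg.se_ratio))
        self.decoder = BasisDecoder(rng, cfg)

    def forward(self, image: Tensor) -> dict:
        feats = self.backbone(image)
        pyr = self.fpn(feats)
        out = dict(feats)
        out.update(pyr)
        for i in range(3, 8):
            out[f"F{i}"] = getattr(self, f"se{i}")(pyr[f"P{i}"])
        out["B"] = self.decoder(out["F3"], out["F4"], out["F5"])
        return out
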