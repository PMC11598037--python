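"""Dual RepVGG feature extractors for the RGB and depth streams.

Each RepVGG block carries parallel 3x3, 1x1 and (stride-1, channel-matched)
identity branches during training, each followed by batch normalisation;
for inference the three branches fold into one 3x3 convolution
(structural reparameterisation).  Activations are SiLU throughout, matching
the activation used in the fusion modules.

The depth stream is fed through a multi-scale stem (parallel 1x1 and 3x3
convolutions, summed) before its RepVGG stages, since single-channel depth
carries less texture than RGB.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

#: stage widths, RepVGG-A-flavoured; the reduced test configs scale these down
DEFAULT_WIDTHS = (48, 96, 192, 384)
DEFAULT_DEPTHS = (2, 2, 2, 2)


class RepVGGBlock(nn.Module):
    """One reparameterisable conv block.

    Train form: act(BN(conv3x3(x)) + BN(conv1x1(x)) + BN(x) [if identity]).
    Deploy form: act(conv3x3_fused(x)).
    """

    def __init__(self, in_ch: int, out_ch: int, stride: int = 1,
                 identity: bool | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if identity and (stride != 1 or in_ch != out_ch):
            raise ValueError("identity branch requires stride 1 and matching channels")
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self.conv3 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        self.conv1 = nn.Conv2d(in_ch, out_ch, 1, stride=stride, padding=0,
                               bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.has_identity = (in_ch == out_ch and stride == 1) \
            if identity is None else bool(identity)
        if self.has_identity:
            self.bnid = nn.BatchNorm2d(out_ch)
        self.deploy = False
        self.fused = None  # nn.Conv2d after reparameterisation

    def forward(self, x: Tensor) -> Tensor:
        if self.deploy:
            if self.fused is None:
                raise RuntimeError("deploy mode requires reparameterize() first")
            return self.fused(x).silu()
        out = self.bn3(self.conv3(x)) + self.bn1(self.conv1(x))
        if self.has_identity:
            out = out + self.bnid(x)
        return out.silu()

    # -- reparameterisation ---------------------------------------------------
    @staticmethod
    def _fold_bn(kernel: np.ndarray, bn: nn.BatchNorm2d):
        """Fold BN running stats into a conv kernel; returns kernel, bias."""
        std = np.sqrt(bn.running_var + bn.eps)
        scale = (bn.weight.data / std).astype(np.float32)
        k = kernel * scale[:, None, None, None]
        b = (bn.bias.data - bn.running_mean * scale).astype(np.float32)
        return k, b

    def fuse_branches(self):
        """Return the equivalent single 3x3 kernel and bias."""
        k3, b3 = self._fold_bn(self.conv3.weight.data, self.bn3)
        k1 = np.zeros_like(self.conv3.weight.data)
        k1[:, :, 1:2, 1:2] = self.conv1.weight.data
        k1, b1 = self._fold_bn(k1, self.bn1)
        kernel, bias = k3 + k1, b3 + b1
        if self.has_identity:
            kid = np.zeros_like(self.conv3.weight.data)
            for c in range(self.out_ch):
                kid[c, c, 1, 1] = 1.0
            kid, bid = self._fold_bn(kid, self.bnid)
            kernel, bias = kernel + kid, bias + bid
        return kernel, bias

    def reparameterize(self):
        """Fuse the branches into one 3x3 conv and switch to deploy mode."""
        if self.deploy:
            return self  # idempotent
        kernel, bias = self.fuse_branches()
        fused = nn.Conv2d(self.in_ch, self.out_ch, 3, stride=self.stride,
                          padding=1, bias=True)
        fused.weight.data = kernel
        fused.bias.data = bias
        self.fused = fused
        self.deploy = True
        return self


class DepthStem(nn.Module):
    """Parallel 1x1 + 3x3 convolutions on the single depth channel, summed."""

    def __init__(self, out_ch: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = nn.Conv2d(1, out_ch, 1, padding=0, rng=rng)
        self.conv3 = nn.Conv2d(1, out_ch, 3, padding=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != 1:
            raise ValueError(f"depth stem expects 1 channel, got {x.shape[1]}")
        return self.conv1(x) + self.conv3(x)


class RepVGGStream(nn.Module):
    """Stem + 4 stages; returns stage features at strides 4, 8, 16, 32."""

    def __init__(self, in_ch: int, widths=DEFAULT_WIDTHS, depths=DEFAULT_DEPTHS,
                 stem_ch: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        stem_ch = stem_ch or widths[0]
        self.stem = RepVGGBlock(in_ch, stem_ch, stride=2, rng=rng)  # /2
        self.stages = nn.ModuleList()
        prev = stem_ch
        for w, n in zip(widths, depths):
            blocks = nn.ModuleList()
            for b in range(n):
                blocks.append(RepVGGBlock(prev, w, stride=2 if b == 0 else 1,
                                          rng=rng))
                prev = w
            self.stages.append(blocks)

    def forward(self, x: Tensor):
        x = self.stem(x)
        feats = []
        for blocks in self.stages:
            for blk in blocks:
                x = blk(x)
            feats.append(x)
        return feats

    def forward_stage(self, x: Tensor, stage: int) -> Tensor:
        """Run one stage (0-based); stage -1 means the stem."""
        if stage == -1:
            return self.stem(x)
        for blk in self.stages[stage]:
            x = blk(x)
        return x

    def reparameterize(self):
        for m in self.modules():
            if isinstance(m, RepVGGBlock):
                m.reparameterize()
        return self


class DualBackbone(nn.Module):
    """RGB stream + depth stream (with multi-scale stem), shape-matched
    per stage so the cross-modal rectification can mix them."""

    def __init__(self, widths=DEFAULT_WIDTHS, depths=DEFAULT_DEPTHS,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.widths = tuple(widths)
        self.rgb_stream = RepVGGStream(3, widths, depths, rng=rng)
        self.depth_stem = DepthStem(widths[0] // 2 or 1, rng=rng)
        self.depth_stream = RepVGGStream(widths[0] // 2 or 1, widths, depths,
                                         rng=rng)

    def forward(self, rgb: Tensor, depth: Tensor):
        """Plain dual forward (no cross-modal rectification); returns a list
        of four (f_rgb, f_d) pairs at strides 4, 8, 16, 32."""
        if rgb.shape[1] != 3:
            raise ValueError("rgb input must have 3 channels")
        if depth.shape[1] != 1:
            raise ValueError("depth input must have 1 channel")
        if rgb.shape[2:] != depth.shape[2:]:
            raise ValueError("rgb and depth spatial shapes differ")
        f_rgb = self.rgb_stream(rgb)
        f_d = self.depth_stream(self.depth_stem(depth))
        return list(zip(f_rgb, f_d))

    def reparameterize(self):
        self.rgb_stream.reparameterize()
        self.depth_stream.reparameterize()
        return self
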