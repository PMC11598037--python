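"""Cross-modal feature rectification (FRM) and squeeze-and-excitation
fusion (SEF).

FRM computes channel weights from pooled statistics of the concatenated
RGB/depth pair (GAP and GMP -> two 2C vectors -> MLP 4C -> C -> 2C ->
sigmoid -> split) and spatial weights from two stacked 1x1 convolutions
(2C -> C/2 -> 2 -> sigmoid -> split), then rectifies each modality with the
*other* modality's feature scaled by the other modality's weights:

    F_rgb_out = F_rgb + 0.5 * F_d * w_d_channel + 0.5 * F_d * w_d_spatial
    F_d_out   = F_d   + 0.5 * F_rgb * w_rgb_channel + 0.5 * F_rgb * w_rgb_spatial

SEF squeezes each rectified stream to a per-channel SE weight and
cross-multiplies (RGB features scaled by the depth SE weight and vice
versa); the merged map goes through a residual pair of branches,
SiLU(BN(1x1-conv(SCConv(.)))) + BN(.).

SCConv is treated as a pluggable redundancy-reducing operator: a spatial
reconstruction unit (group-norm scale gating with cross reconstruction)
followed by a channel reconstruction unit (split, group-wise vs pointwise
transform, pooled soft-attention fuse).  All activations are SiLU.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor, concat


def _gap(x: Tensor) -> Tensor:
    """Global average pool to (N, C)."""
    return x.mean(axis=(2, 3))


def _gmp(x: Tensor) -> Tensor:
    """Global max pool to (N, C)."""
    return x.max(axis=(2, 3))


def _check_pair(f_rgb: Tensor, f_d: Tensor):
    if f_rgb.shape != f_d.shape:
        raise ValueError(f"modal shapes differ: {f_rgb.shape} vs {f_d.shape}")


class FeatureRectification(nn.Module):
    """FRM for one backbone stage with C channels per modality."""

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        if channels % 4:
            raise ValueError("FRM channel count must be divisible by 4")
        c = channels
        self.channels = c
        # channel path: concat(GAP, GMP) of the 2C stack -> 4C -> C -> 2C
        self.fc1 = nn.Linear(4 * c, c, rng=rng)
        self.fc2 = nn.Linear(c, 2 * c, rng=rng)
        # spatial path: 2C -> C/2 -> 2 with 1x1 convs
        self.sconv1 = nn.Conv2d(2 * c, c // 2, 1, rng=rng)
        self.sconv2 = nn.Conv2d(c // 2, 2, 1, rng=rng)

    def channel_weights(self, f_rgb: Tensor, f_d: Tensor):
        """Per-channel weight vectors (each (N, C), sigmoid range)."""
        _check_pair(f_rgb, f_d)
        stacked = concat([f_rgb, f_d], axis=1)                  # (N, 2C, H, W)
        pooled = concat([_gap(stacked), _gmp(stacked)], axis=1)  # (N, 4C)
        w = self.fc2(self.fc1(pooled).silu()).sigmoid()          # (N, 2C)
        c = self.channels
        return w[:, :c], w[:, c:]

    def spatial_weights(self, f_rgb: Tensor, f_d: Tensor):
        """Two (N, 1, H, W) weight maps in sigmoid range."""
        _check_pair(f_rgb, f_d)
        stacked = concat([f_rgb, f_d], axis=1)
        w = self.sconv2(self.sconv1(stacked).silu()).sigmoid()   # (N, 2, H, W)
        return w[:, 0:1], w[:, 1:2]

    def forward(self, f_rgb: Tensor, f_d: Tensor):
        w_rgb_c, w_d_c = self.channel_weights(f_rgb, f_d)
        w_rgb_s, w_d_s = self.spatial_weights(f_rgb, f_d)
        n, c = w_d_c.shape
        w_d_c = w_d_c.reshape(n, c, 1, 1)
        w_rgb_c = w_rgb_c.reshape(n, c, 1, 1)
        out_rgb = f_rgb + 0.5 * f_d * w_d_c + 0.5 * f_d * w_d_s
        out_d = f_d + 0.5 * f_rgb * w_rgb_c + 0.5 * f_rgb * w_rgb_s
        return out_rgb, out_d


class SqueezeExcite(nn.Module):
    """Classic SE bottleneck producing per-channel sigmoid weights."""

    def __init__(self, channels: int, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        w = self.fc2(self.fc1(_gap(x)).silu()).sigmoid()   # (N, C)
        n, c = w.shape
        return w.reshape(n, c, 1, 1)


class SRU(nn.Module):
    """Spatial reconstruction unit: gate channels by the normalised
    group-norm scale, split into informative / less-informative groups and
    cross-reconstruct."""

    def __init__(self, channels: int, groups: int = 4,
                 gate_threshold: float = 0.5):
        super().__init__()
        self.gn = nn.GroupNorm(min(groups, channels), channels)
        self.gate_threshold = gate_threshold
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        gn_x = self.gn(x)
        gamma = self.gn.weight
        w_gamma = gamma * (gamma.abs().sum() + 1e-12) ** -1.0   # (C,)
        n, c = x.shape[0], self.channels
        reweights = (gn_x * w_gamma.reshape(1, c, 1, 1)).sigmoid()
        # hard split mask (constant w.r.t. gradients)
        info = (reweights.data >= self.gate_threshold).astype(np.float32)
        x1 = reweights * Tensor(info) * gn_x
        x2 = reweights * Tensor(1.0 - info) * gn_x
        h = c // 2
        # cross reconstruction between the two halves
        out_a = x1[:, :h] + x2[:, h:]
        out_b = x1[:, h:] + x2[:, :h]
        return concat([out_a, out_b], axis=1)


class CRU(nn.Module):
    """Channel reconstruction unit: split channels (ratio 1/2), transform one
    part group-wise and the other pointwise, fuse with pooled soft attention."""

    def __init__(self, channels: int, groups: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels % 2:
            raise ValueError("CRU needs an even channel count")
        half = channels // 2
        g = groups if half % groups == 0 else 1
        self.gwc = nn.Conv2d(half, channels, 3, padding=1, groups=g, rng=rng)
        self.pwc1 = nn.Conv2d(half, channels, 1, rng=rng)
        self.pwc2 = nn.Conv2d(half, half, 1, rng=rng)
        self.half = half
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        up, low = x[:, :self.half], x[:, self.half:]
        y1 = self.gwc(up) + self.pwc1(up)                       # (N, C, H, W)
        y2 = concat([self.pwc2(low), low], axis=1)              # (N, C, H, W)
        # pooled soft attention over the two branches
        s1, s2 = _gap(y1), _gap(y2)                             # (N, C)
        e1 = (s1 - s1.max(axis=1, keepdims=True).detach()).exp()
        e2 = (s2 - s2.max(axis=1, keepdims=True).detach()).exp()
        # softmax across branches, per channel
        b1 = e1 * (e1 + e2) ** -1.0
        b2 = e2 * (e1 + e2) ** -1.0
        n, c = s1.shape
        return y1 * b1.reshape(n, c, 1, 1) + y2 * b2.reshape(n, c, 1, 1)


class SCConv(nn.Module):
    """Spatial + channel reconstruction, shape preserving."""

    def __init__(self, channels: int, groups: int = 4, gate_threshold: float = 0.5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.sru = SRU(channels, groups=groups, gate_threshold=gate_threshold)
        self.cru = CRU(channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.cru(self.sru(x))


class SqueezeExciteFusion(nn.Module):
    """SEF: cross-applied SE attention plus a residual SCConv merge."""

    def __init__(self, channels: int, reduction: int = 4,
                 scconv: nn.Module | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.se_rgb = SqueezeExcite(channels, reduction, rng=rng)
        self.se_d = SqueezeExcite(channels, reduction, rng=rng)
        self.scconv = scconv if scconv is not None else SCConv(channels, rng=rng)
        self.conv = nn.Conv2d(channels, channels, 1, rng=rng)
        self.bn_main = nn.BatchNorm2d(channels)
        self.bn_skip = nn.BatchNorm2d(channels)

    def forward(self, f_rgb: Tensor, f_d: Tensor) -> Tensor:
        _check_pair(f_rgb, f_d)
        w_rgb = self.se_rgb(f_rgb)
        w_d = self.se_d(f_d)
        w_mid = f_rgb * w_d + f_d * w_rgb      # cross assignment
        main = self.bn_main(self.conv(self.scconv(w_mid))).silu()
        return main + self.bn_skip(w_mid)
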