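"""Neural-network layers on top of the autodiff tensors.

Layout conventions follow the common NCHW deep-learning ones: convolution
weights are (out, in/groups, kh, kw), transposed-convolution weights are
(in, out, kh, kw), linear weights are (out, in).
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor

__all__ = [
    "Module", "ModuleList", "Sequential", "Conv2d", "ConvTranspose2d",
    "Linear", "BatchNorm2d", "GroupNorm", "SiLU", "ReLU", "Identity",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def num_parameters(self, trainable_only: bool = True) -> int:
        return sum(p.size for p in self.parameters()
                   if p.requires_grad or not trainable_only)

    def freeze(self, flag: bool = True):
        for p in self.parameters():
            p.requires_grad = not flag
        return self

    # buffers (running stats) are plain ndarray attributes named in _buffers
    _buffer_names: tuple = ()

    def state_dict(self, prefix: str = "") -> dict:
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                out[prefix + name] = val.data.copy()
        for bname in self._buffer_names:
            out[prefix + bname] = np.array(getattr(self, bname))
        for name, child in self._children():
            out.update(child.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                val.data = np.asarray(state[prefix + name], dtype=np.float32).copy()
        for bname in self._buffer_names:
            setattr(self, bname, np.asarray(state[prefix + bname]).copy())
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + ".")


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(ModuleList):
    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels not divisible by groups")
        rng = rng or np.random.default_rng()
        fan_in = (in_ch // groups) * kernel * kernel
        self.stride, self.padding, self.groups = stride, padding, groups
        self.weight = Parameter(_kaiming(rng, (out_ch, in_ch // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 2,
                 padding: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        fan_in = in_ch * kernel * kernel
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_kaiming(rng, (in_ch, out_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose2d(self.weight, self.bias, stride=self.stride,
                                  padding=self.padding)

    def set_bilinear(self):
        """Initialise the kernel to the classic bilinear-upsampling weights."""
        c_in, c_out, k, _ = self.weight.data.shape
        factor = (k + 1) // 2
        center = factor - 1 if k % 2 == 1 else factor - 0.5
        og = np.arange(k)
        f = (1 - np.abs(og - center) / factor)
        kern = np.outer(f, f).astype(np.float32)
        w = np.zeros_like(self.weight.data)
        for c in range(min(c_in, c_out)):
            w[c, c] = kern
        self.weight.data = w
        if self.bias is not None:
            self.bias.data[:] = 0
        return self


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(_kaiming(rng, (out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalisation over (N, H, W) per channel.

    With `use_batch_stats_in_eval` the layer normalises with the current
    batch statistics even in eval mode (free-running BN): with very small
    batches the running averages are a poor match for the statistics the
    layers were trained under, and detection quality collapses with them.
    Running stats are still tracked for reparameterisation.
    """

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, ch: int, eps: float = 1e-5, momentum: float = 0.1,
                 use_batch_stats_in_eval: bool = False):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.use_batch_stats_in_eval = use_batch_stats_in_eval
        self.weight = Parameter(np.ones(ch, dtype=np.float32))
        self.bias = Parameter(np.zeros(ch, dtype=np.float32))
        self.running_mean = np.zeros(ch, dtype=np.float32)
        self.running_var = np.ones(ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training or self.use_batch_stats_in_eval:
            m = x.mean(axis=(0, 2, 3), keepdims=True)
            v = ((x - m) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            if self.training:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * m.data.ravel())
                n = x.size / x.shape[1]
                unbias = n / max(n - 1, 1)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * v.data.ravel() * unbias)
            xhat = (x - m) * ((v + self.eps) ** -0.5)
        else:
            m = self.running_mean.reshape(1, -1, 1, 1)
            v = self.running_var.reshape(1, -1, 1, 1)
            xhat = (x - m) * ((v + self.eps) ** -0.5)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class GroupNorm(Module):
    def __init__(self, groups: int, ch: int, eps: float = 1e-5):
        super().__init__()
        if ch % groups:
            raise ValueError("channels not divisible by groups")
        self.groups, self.eps = groups, eps
        self.weight = Parameter(np.ones(ch, dtype=np.float32))
        self.bias = Parameter(np.zeros(ch, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        N, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(N, g, C // g * H * W)
        m = xg.mean(axis=2, keepdims=True)
        v = ((xg - m) ** 2.0).mean(axis=2, keepdims=True)
        xhat = ((xg - m) * ((v + self.eps) ** -0.5)).reshape(N, C, H, W)
        return xhat * self.weight.reshape(1, -1, 1, 1) + self.bias.reshape(1, -1, 1, 1)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
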