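"""Module system: parameter registration, conv/BN building blocks, profiling.

Layout conventions follow the YOLO lineage: activations are NCHW float32,
convolution weights are OIHW, and every backbone/neck convolution is a
bias-free conv + BatchNorm + SiLU triple (the "Convs" block).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

_PROFILE: list | None = None


class profile_record:
    """Context manager collecting per-conv MAC records during a forward pass."""

    def __init__(self):
        self.records: list[dict] = []

    def __enter__(self):
        global _PROFILE
        _PROFILE = self.records
        return self

    def __exit__(self, *exc):
        global _PROFILE
        _PROFILE = None
        return False


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class with automatic parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for k, b in self._buffers.items():
            yield prefix + k, b
        for k, m in self._modules.items():
            yield from m.named_buffers(prefix + k + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- (de)serialisation -------------------------------------------------

    def state_dict(self) -> dict:
        d = {k: p.data.copy() for k, p in self.named_parameters()}
        d.update({k: b.copy() for k, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in d.items():
            if k in own:
                if own[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}: {own[k].data.shape} vs {v.shape}")
                own[k].data[...] = v
            elif k in bufs:
                bufs[k][...] = v
            else:
                raise KeyError(f"unexpected entry in state dict: {k}")
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


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


class Conv2d(Module):
    """Plain 2-D convolution; He-normal init, optional bias (zero init)."""

    def __init__(self, cin: int, cout: int, kernel: int = 1, stride: int = 1,
                 padding: int | None = None, bias: bool = True, rng=None):
        super().__init__()
        self.cin, self.cout, self.kernel, self.stride = cin, cout, kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * kernel * kernel))
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin, kernel, kernel)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)
        if _PROFILE is not None:
            n, _, ho, wo = out.data.shape
            _PROFILE.append({
                "macs_per_pixel": self.cin * self.kernel * self.kernel * self.cout,
                "out_pixels": ho * wo,
                "bias_elems": (self.cout * ho * wo) if self.bias is not None else 0,
            })
        return out


class BatchNorm2d(Module):
    """Batch norm over (N, H, W); momentum/eps as in the YOLOv5 lineage."""

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self._buffers["running_mean"] = np.zeros(channels, dtype=np.float32)
        self._buffers["running_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        c = x.data.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            m = self.momentum
            rm *= 1 - m
            rm += m * mu.data.reshape(-1)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            rv *= 1 - m
            rv += m * unbiased
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class ConvBnSiLU(Module):
    """The standard 'Convs' block: bias-free conv + BN + SiLU."""

    def __init__(self, cin, cout, kernel=1, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).silu()


class SGD:
    """SGD with momentum and decoupled-from-gradients weight decay.

    Matches the classic update: v <- m*v + g + wd*w ; w <- w - lr*v.
    """

    def __init__(self, params, lr: float, momentum: float = 0.937,
                 weight_decay: float = 5e-4):
        self.params = list(params)
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None
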