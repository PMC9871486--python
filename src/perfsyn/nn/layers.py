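"""Layer / module system over the autodiff core.

Mirrors the torch ``nn.Module`` idiom at a much smaller scale: modules hold
``Parameter`` tensors and submodules as attributes, ``parameters()`` walks
them recursively, ``state_dict`` / ``load_state_dict`` move plain numpy
arrays in and out for checkpointing.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, batch_norm, conv2d, conv3d, conv_transpose2d

DTYPE = np.float32
INIT_STD = 0.02  # pix2pix-style normal(0, 0.02) weight init


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)


class Module:
    training: bool = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        out = []
        for _, p in self.named_parameters():
            out.append(p)
        return out

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {name: p.data.copy() for name, p in self.named_parameters()}
        d.update({name: b.copy() for name, b in self.named_buffers()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(d)
        if missing:
            raise KeyError(f"state dict missing entries: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != d[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: model {p.data.shape}, checkpoint {d[name].shape}"
                )
            p.data = d[name].astype(DTYPE).copy()
        for name, b in bufs.items():
            if b.shape != d[name].shape:
                raise ValueError(f"shape mismatch for buffer {name}")
            b[...] = d[name]


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _init(rng: np.random.Generator, shape) -> np.ndarray:
    return rng.normal(0.0, INIT_STD, size=shape)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel=4, stride=2, padding=1, bias=True, *, rng):
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_init(rng, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in, c_out, kernel=4, stride=2, padding=1, bias=True, *, rng):
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_init(rng, (c_in, c_out, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias, self.stride, self.padding)


class Conv3d(Module):
    """Input layout (N, C, T, H, W); kernel/stride/padding ordered (t, h, w)."""

    def __init__(self, c_in, c_out, kernel=(4, 3, 3), stride=(2, 1, 1), padding=(1, 1, 1), bias=True, *, rng):
        self.stride, self.padding = stride, padding
        self.weight = Parameter(_init(rng, (c_out, c_in) + tuple(kernel)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm(Module):
    """Works for (N,C,H,W) and (N,C,T,H,W) inputs alike.

    Following pix2pix practice, inference normalizes with the statistics of
    the batch being generated (run generation at batch size 1 for strictly
    per-sample behavior) rather than the training running averages, which at
    batch size 4 track the data too loosely to transfer; set
    ``use_batch_stats_in_eval=False`` for classic running-average inference.
    Running buffers are still maintained and checkpointed either way.
    """

    def __init__(self, c, momentum=0.1, eps=1e-5, use_batch_stats_in_eval=True, *, rng):
        self.momentum, self.eps = momentum, eps
        self.use_batch_stats_in_eval = use_batch_stats_in_eval
        self.gamma = Parameter(rng.normal(1.0, INIT_STD, size=c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)

    def forward(self, x):
        if self.training:
            return batch_norm(
                x, self.gamma, self.beta, self.running_mean, self.running_var,
                True, self.momentum, self.eps,
            )
        if self.use_batch_stats_in_eval:
            # batch statistics without touching the running buffers
            return batch_norm(
                x, self.gamma, self.beta, self.running_mean.copy(), self.running_var.copy(),
                True, 0.0, self.eps,
            )
        return batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            False, self.momentum, self.eps,
        )


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Dropout(Module):
    """Inverted dropout; the implicit GAN noise source when rate > 0."""

    def __init__(self, rate: float, *, rng):
        self.rate = rate
        self._rng = rng

    def forward(self, x):
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self._rng.random(x.data.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)
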